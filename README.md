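# clonesense

Statistics for clonal **fragmentation** and **merging** in genetic
lineage-tracing experiments.

In lineage tracing, a subset of cells is heritably labelled (often with a
multicolor construct such as Confetti) and the sizes and positions of the
resulting clones are read out later.  The interpretation rests on a strict
one-to-one link between an observed cluster of labelled cells and a single
induced founder cell.  That link breaks in two ways: clones of the same
color can **merge** into one cluster (making clusters polyclonal), and one
clone can **fragment** into several spatially separated clusters (through
tissue rearrangement, division pushing, or cell intercalation).  Undetected,
both processes push clone-size distributions toward universal shapes that
carry no information about cell fate.

`clonesense` implements the statistical toolkit for detecting, quantifying
and correcting these effects, validated end-to-end against a built-in
spatially explicit Monte Carlo simulator with ground truth:

| module | what it does |
| --- | --- |
| `clonedata` | domain types (color schemes, cluster tables, count summaries, size laws) and CSV/TSV IO |
| `induction` | induction frequency m₀ from multicolor color counts: C_n ∝ Binom(n_C, 1−e^(−m₀)); ratio inversion m₀ = log(1 + (n+1)/(n_C−n) · C_{n+1}/C_n) and a pooled multinomial MLE; region partitioning for large tissues |
| `merging` | multicolor unicolor-merger estimate G(c) ≈ (k_bicolor/k) · r_c / (1 − Σ r_c²); single-color estimates from the labelled area fraction, the 1D geometric argument, and the d-dimensional nearest-neighbour overlap integral ∫(1 − e^(−ρV_d(r)))C(r)dr |
| `multipotency` | exact binomial tests of same-color basal–luminal pairing against chance-merger nulls, with pairwise (ν = Σ r_C^A r_C^B) and contact (coordination-number) null models |
| `fragmentation` | joint Poisson model J(k,m) of induction and fragmentation, fragment-count law F(k), maximum-likelihood (m₀, f), and the likelihood-ratio monoclonality filter Λ(k) |
| `restoration` | Bayesian distance threshold w* for re-joining fragments, single-linkage clone restoration, Moran's I spatial autocorrelation |
| `simulate` | the Monte Carlo generator: Poisson induction, multinomial colors, configurable clone-size laws, Poisson fragmentation with dispersal, geometric merger ground truth |

A thin CLI (`clonesense induction|merge|multipotency|fragments|restore|morans-i|simulate`)
wraps the library for shell use; the `examples/` directory holds short
narrative scripts, one per capability.

## Worked example

`python examples/04_fragmentation_filter.py` simulates 1300 single-color
samples at m₀ = 1.5 induced clones per sample and f = 0.8 fragmentation
events per clone, then fits f and filters for monoclonal sample-colors:

```
1016 labelled sample-colors, mean fragment count 3.46
fitted fragmentation rate f = 0.791 +/- 0.036 (truth 0.8)
monoclonality cutoff: keep sample-colors with <= 2 fragments; kept 415 of 1016
  Lambda(1) = 0
  Lambda(2) = 0.43
  Lambda(3) = 1.96
  Lambda(4) = 7.53
  Lambda(5) = 29.7
```

The fitted rate recovers the simulation truth within one standard error.
Λ(k) is the posterior odds that k observed fragments derive from more than
one induction event; at the default threshold Λ < 1 only sample-colors with
at most two fragments are kept for downstream clonal analysis — a sample
with three or more fragments is more likely polyclonal than monoclonal at
these rates.

Other quick numbers (see `examples/`): the multicolor merging correction
factor 1 − Σ r_c² is **0.72** for a 30/30/30/10 palette and **0.43** for a
73/17/9/1 palette; 50 same-color pairs out of 100 at ν = 1/3 gives an exact
binomial p-value of **4.2 × 10⁻⁴**; distance-threshold restoration at low
density and f = 0.3 recovers the true clonal partition with Rand index
**0.999**.

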