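# Methods

This note documents the statistical models implemented in `clonesense`,
their assumptions, the parameter conventions, the numerical choices, and
what the simulator-backed validation does and does not demonstrate.

## Observation model and units

The observable unit is the *labelled cell cluster*: a spatially contiguous
group of same-color cells, recorded as one row of a cluster table with its
sample, color, centroid position and cell count.  Coordinates are
real-valued centroids in arbitrary but consistent length units; nothing
assumes a lattice.  Unlabelled samples leave no rows, so every operation
that needs the count of unlabelled samples (C₀) takes it as an explicit
parameter rather than inferring it.

## Induction frequency (module `induction`)

Induction events in different colors are assumed statistically
independent, each color receiving a Poisson number of founder cells with
mean m₀.  A sample is then unlabelled in any one color with probability
J = e^(−m₀), and the number of distinct colors observed among n_C follows
Binomial(n_C, 1 − J); when only labelled samples are recorded the n = 0
class is dropped and the law renormalized by 1 − J^{n_C}.

**m₀ is per color.**  The binomial channel structure forces this reading:
with equal color usage the expected total number of induced cells per
sample is n_C · m₀.  The API exposes both numbers
(`InductionEstimate.m0` and `.m0_total(n_colors)`) because the two are
easily conflated.

Two estimators are provided:

- the *adjacent-ratio* inversion
  m₀ = log(1 + (n+1)/(n_C−n) · C_{n+1}/C_n), with a delta-method standard
  error treating C_n and C_{n+1} as independent Poisson counts.  The
  independence is an acknowledged approximation (the counts are
  multinomially coupled); by default the class index n maximizes
  min(C_n, C_{n+1}) since the ratio's variance is dominated by the smaller
  count.
- the *multinomial MLE*, which pools all classes and remains usable when
  individual classes are empty.  Its standard error comes from the
  observed Fisher information and is the recommended one.  All mass at
  n = n_C makes m₀ unbounded; this is reported as infinity rather than an
  arbitrary large number.

For large tissues, `partition_regions` tiles the bounding box into equal
regions separated by discardable buffer strips, turning one organ into
many approximately independent pseudo-samples.

## Merging probability (module `merging`)

A cluster is polyclonal when two or more same-color clones have joined.

**Multicolor.**  Unicolor mergers are invisible but bicolor contacts are
not.  With independent multinomial color assignment, the unicolor merger
fraction for color c is estimated as
(k_bicolor/k) · r_c / (1 − Σ_c r_c²).  The denominator — the probability
that two independently colored clones differ in color — corrects the
observed cluster count for the mergers hidden in it.  This estimator is
approximate by construction; the simulator shows it is accurate at low
contact density and acquires a downward bias of order the contact fraction
itself once contacts become common (multi-cluster contacts violate the
pairwise bookkeeping).  "Contact" is defined as centroid distance below a
user-supplied radius: cluster tables carry centroids, not polygons, so the
radius is a required argument with no hidden default.

**Single color.**  Three estimators of increasing structure:

1. *Area fraction*: the probability that a randomly placed point-like
   clone lands on labelled tissue equals the labelled area fraction.
   Neglecting the picked clone's own extent biases this low — in the
   simulator it runs at roughly half the realized polyclonal-cluster
   fraction — so it is an order-of-magnitude check, not a precise
   estimate.
2. *1D geometric*: with per-cell induction probability p and clone-size
   law P(s), p_merge = 1 − Σ_s (1−p)^s P(s).
3. *General d (1–3)*: under statistically independent, spatially uniform
   induction and isotropic compact growth, merging is the event that the
   nearest-neighbour centre distance falls below the sum of the two clone
   radii: p_merge = ∫ (1 − e^(−ρ V_d(r))) C(r) dr with clone density
   ρ = m₀/V, V_d the d-ball volume, and C(r) the law of the radius sum.
   Size s maps to radius via V_d(r_s) = s · cell_volume, with cell_volume
   an explicit parameter (default 1).  For a discrete size law C is a
   discrete convolution and the integral is evaluated *exactly* as a
   double sum; an optional Gaussian-kernel smoothing with adaptive
   quadrature (error bound reported) exists for cross-checking and for
   densities supplied on a continuum.  Only pairwise mergers are counted;
   three-clone events are ignored, so at high density the estimate tends
   toward a lower bound.

## Multipotency tests (module `multipotency`)

The evidence that one progenitor produces two cell compartments is k*
same-color (or labelled-contact) pairs among N, tested against the
chance-merger null Binomial(N, ν) with the exact upper tail
p = Σ_{k≥k*} C(N,k) ν^k (1−ν)^{N−k}.

Null pairing probabilities:

- *pairwise*: ν = Σ_C r_C^A r_C^B from the two compartments' color
  frequencies;
- *contact*: ν = Σ_C λ_C Σ_z z (1 − Σλ)^{z−1} F(z) from per-color
  induction probabilities λ_C and the coordination-number distribution
  F(z) (the exactly-one-labelled-neighbour mass), with the small-induction
  approximation ν ≈ z̄ Σλ provided separately.  The approximation's
  relative error is of order Σλ · E[z(z−1)]/z̄ and is validated against
  the exact form.

The tail is summed in log space with exact (compensated) summation, and
whichever tail is numerically smaller is summed and complemented; this
keeps absolute accuracy near machine precision up to N ~ 10⁶.  Accuracy is
cross-checked against the regularized incomplete beta function — an
independent route the implementation never uses.

## Fragmentation model and monoclonality filter (module `fragmentation`)

Induction per sample-and-color is Poisson(m₀); each clone accrues
Poisson(f) fragmentation events, so m clones leave k = m + Poisson(m·f)
fragments.  The joint law is

J(k, m) = (m f)^{k−m}/(k−m)! · m₀^m/m! · e^{−m f − m₀},  k ≥ m,

with the 0⁰ = 1 convention at k = m.  Conditioning on the sample being
labelled gives the observable fragment-count law
F(k) = Σ_{m=1..k} J(k, m)/(1 − J(0,0)) — the unique normalization over
k ≥ 1, verified analytically (Σ_k Σ_m J(k,m) = 1 − e^{−m₀}) and by test.

Fitting maximizes Σ log F(k_i) over f (with m₀ fixed from an independent
multicolor estimate — the recommended path) or jointly over (m₀, f).  The
joint surface is near-degenerate along induction-fragmentation trade-offs;
the fit reports observed-Fisher standard errors and flags a flat surface
via the Hessian condition number.  Optimization runs on log-parameters
(bounded scalar search when m₀ is fixed; Nelder–Mead from three
deterministic starts jointly).  All fragment counts of 1 put f̂ on the
boundary at 0.

The monoclonality filter uses the posterior odds
Λ(k) = Σ_{m≥2} J(k,m)/J(k,1), strictly increasing in k, with Λ(1) = 0.
Sample-colors with fragment counts above the largest k satisfying
Λ(k) < threshold (default 1: "more likely monoclonal than not") are
discarded; an audit table records every decision.  Fragments are counted
per (sample, color).

## Clonality restoration and Moran's I (module `restoration`)

Two same-color clusters are linked when their centroid distance is below

w* = [Γ(d/2+1) V/(π^{d/2} k f) · |ln(1 − α e^{−f})|]^{1/d},

which decreases in the fragmentation rate f and the observed cluster count
k; α = 0.5 is the default significance level (below w* a pair is more
likely clonal than polyclonal).  The absolute value makes the printed
closed form real (the logarithm is negative) and preserves the stated
monotonicities.  Two known inconsistencies in the source derivation are
documented rather than resolved: the prose identifies the prior
fragmentation probability with e^f, which exceeds 1, and the conditional
distance law is written as a survival function rather than a density.  The
implementation adopts the closed form as printed;
`clonal_distance_probability` exposes the nearest-neighbour survival
P(w|m=2) = e^{−ρ V_d(w)} together with an α-level function
e^f (1 − e^{−ρ f V_d(w)}) (ρ = k/V, the observed cluster density) whose
root at level α reproduces w* exactly, so the threshold can be audited by
root finding.

Restoration is *single linkage* (union-find over all same-sample,
same-color pairs within w*): the derivation concerns nearest-neighbour
pair distances, which single linkage respects and complete linkage does
not.  Clone labels are the lexicographically smallest member id, making
the partition invariant under row order and rigid motions.  Colors never
join across, and merged clusters are never split (merging-aware
restoration is out of scope).  A future posterior-based backend can slot
behind the same `ClonalPartition` interface.

Moran's I uses the standard cross-product form over a user-built weight
matrix (k-nearest-neighbour or distance band).  Weight builders
row-standardize by default, following common spatial-statistics practice;
binary weights are available by flag, and the statistic itself accepts any
nonnegative zero-diagonal matrix.

## The simulator (module `simulate`)

Per sample: m ~ Poisson(m₀) clones placed uniformly in a d-dimensional box
(d = 1–3), colors multinomial from the scheme, sizes from a configurable
law (fixed; geometric — the stationary/homeostatic proxy; exponential-mean
via ⌈Exp⌉ — an expansion-like proxy), fragments 1 + Poisson(f) per clone
with the clone's cells split by a uniform random composition (no
biological splitting law is established, so the maximum-entropy choice is
used) and fragment centroids displaced isotropically (Gaussian, scale
`dispersal`).  Boundaries are periodic by default to keep
nearest-neighbour statistics free of edge bias (switchable).  Ground truth
records every fragment's clone and all same-color geometric contacts
(disks of compact-clone radius overlapping, minimum-image metric).

Deliberate idealizations — what passing tests do *not* show about real
data: clones are isotropic disks (no elongated stripes or envelopes),
fragmentation is a single Poisson count with one dispersal scale (no
time-resolved kinetics or directed flows), colors are exchangeable within
a scheme, and a clone cannot split into more fragments than it has cells
(the analytic fragment law has no such cap, so validation runs use clone
sizes large enough that the cap never binds).  Real tissues violate each
of these to some degree; the simulator validates the estimators under
their own stated assumptions, not under tissue realism.

## Validation problem sizes and numerical tolerances

Chosen once as the package's validation conditions: the fragment-count law
is checked by chi-square against 10⁵ simulated samples (tail bins pooled
to expected counts ≥ 5); fragmentation-rate recovery uses ~10³
sample-colors at (m₀, f) = (1.5, 0.8) with a 2-standard-error band; the
nearest-neighbour merging integral is checked against a 400-realization
disk-overlap Monte Carlo at ρV_d(2r̄) ≈ 0.1 within 3σ; restoration is
benchmarked at low density and f = 0.3 with a Rand-index bar of 0.9;
Moran's I is compared to the brute-force double sum at 10⁻¹² and to the
−1/(n−1) null within 3σ of the normality variance.  Distribution objects
validate normalization to 10⁻⁹; truncated analytic laws (geometric sizes)
cut the tail at 10⁻¹² mass and renormalize.  MLE convergence tolerances
are 10⁻¹⁰–10⁻⁸ in log-likelihood.  Exact binomial tails are accurate to
~10⁻¹² absolute for the regimes tested (the gammaln route limits per-term
relative accuracy to ~10⁻⁹ at N ~ 10⁶, which the smaller-tail complement
strategy converts into a negligible absolute error away from the mode).

## Known limitations

- Eq.-3-style multicolor correction is first-order in the contact
  fraction; no error bound beyond the simulator evidence is available.
- The area-fraction estimate is a deliberate heuristic (documented bias
  ~2× low).
- The general-d merging integral ignores ≥3-clone events (lower-bound
  tendency at high density) and percolation regimes entirely.
- The monoclonality filter inherits the Poisson induction assumption; over-
  dispersed induction would shift Λ.
- Restoration cannot split merged clusters and never joins across colors.
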