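"""Estimate clonal merging probabilities, multicolor and single-color.

The multicolor path counts bicolor contacts in simulated data and rescales
them with the correction factor 1 - sum r_c^2; the single-color path
evaluates the nearest-neighbour overlap integral from the induction
frequency and the clone-size distribution alone.
"""

import clonesense as cs

# -- multicolor: bicolor contacts reveal invisible unicolor mergers
scheme = cs.ColorScheme(("CFP", "RFP", "YFP", "GFP"), (0.3, 0.3, 0.3, 0.1))
print(f"correction factor 1 - sum r_c^2 = {cs.correction_factor(scheme):.2f}")

cfg = cs.SimConfig(seed=7, d=2, volume=3000.0, m0=12.0, scheme=scheme,
                   size_model=cs.SizeModel("fixed", 6), f=0.0,
                   dispersal=0.0, n_samples=500)
table, truth = cs.simulate(cfg)
contact_radius = 2 * cs.clone_radius(6, 1.0, 2)
contacts = cs.count_bicolor_contacts(table, contact_radius)
for color, (k_bicolor, k) in sorted(contacts.items()):
    est = cs.unicolor_merger_fraction(k_bicolor, k, color, scheme)
    print(f"  {color}: {k_bicolor}/{k} bicolor contacts -> "
          f"unicolor merger fraction {est.p_merge:.3f}")
in_merger = {c for pair in truth.merger_pairs for c in pair}
print(f"ground truth: {len(in_merger) / len(table):.3f} of clusters are in "
      "same-color contact")

# -- single color: Poisson nearest-neighbour overlap integral
sizes = cs.CloneSizeDistribution.geometric(5)
est = cs.merge_prob_general(m0=20.0, volume=4000.0, d=2, sizes=sizes)
print(f"single-color nearest-neighbour estimate: p_merge = {est.p_merge:.3f}")
# This is the probability that a cluster is polyclonal; at this density
# about one cluster in eleven hides a merger.
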