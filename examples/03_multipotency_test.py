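"""Test multipotency against the chance-merger null.

With three equally used colors a labelled basal-luminal pair shares its
color by chance with probability nu = 1/3.  Observing 50 same-color pairs
among 100 is then decisive evidence for a shared (bipotent) progenitor.
"""

import clonesense as cs

scheme = cs.ColorScheme.equal(("RFP", "YFP", "CFP"))
nu = cs.nu_pairwise(scheme, scheme)
print(f"pairwise null: nu = {nu.nu:.4f}")

result = cs.binomial_multipotency_test(k_star=50, N=100, nu=nu)
print(f"k* = 50 of N = 100 same-color pairs -> p = {result.p_value:.2g}")
# p ~= 4e-4: chance mergers alone produce this many unicolor pairs in
# fewer than one experiment in a thousand.

# the contact variant: induced basal cells touching labelled luminal cells
coord = cs.CoordinationDistribution({2: 0.25, 3: 0.5, 4: 0.25})
lambdas = {"RFP": 0.03, "YFP": 0.03, "CFP": 0.03}
nu_c = cs.nu_contact(lambdas, coord)
nu_a = cs.nu_contact_approx(lambdas, coord.mean())
print(f"contact null: nu = {nu_c.nu:.4f} (exact), {nu_a.nu:.4f} (z-bar approx)")
result2 = cs.binomial_multipotency_test(k_star=60, N=150, nu=nu_c)
print(f"k* = 60 of N = 150 labelled contacts -> p = {result2.p_value:.2g}")
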