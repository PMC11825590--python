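"""The per-well statistical engine on small explicit inputs.

The Mann-Whitney branch enumerates every assignment of the pooled values
exactly (tie-aware) for small designs such as 2 patients vs 50 controls;
the Benjamini-Hochberg step-up turns per-well p-values into q-values.
"""

import math

import numpy as np

from pmprofile import benjamini_hochberg, mann_whitney_two_sided

# the smallest achievable two-sided exact p for 2 cases vs 50 controls
rng = np.random.default_rng(0)
controls = rng.normal(2.5, 0.07, size=50)
cases = np.array([2.0, 2.05])  # far below every control
res = mann_whitney_two_sided(cases, controls)
print(f"2 vs 50, fully separated: U = {res.u_stat}, p = {res.p:.6g} ({res.method})")
print(f"   minimum achievable: 2 / C(52,2) = {2 / math.comb(52, 2):.6g}")

# a tied, overlapping design
a = [1, 1, 2, 3]
b = [1, 2, 2, 4]
res = mann_whitney_two_sided(a, b)
print(f"tied 4 vs 4: U = {res.u_stat}, exact p = {res.p:.4g}")

# Benjamini-Hochberg over a toy family of 6 wells
p_values = [0.001, 0.008, 0.039, 0.041, 0.5, 0.9]
p_adj, flags = benjamini_hochberg(p_values, q=0.05)
print("\n well    p      q-value  significant(q<0.05)")
for i, (p, pa, f) in enumerate(zip(p_values, p_adj, flags)):
    print(f"   {i}   {p:<7g}{pa:<9.4g}{bool(f)}")
# Only the wells whose step-up adjusted value stays under q are kept:
# multiplicity control trims the two raw-significant borderline wells.
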