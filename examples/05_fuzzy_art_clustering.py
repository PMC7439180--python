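"""Fuzzy ART basics: complement coding, vigilance, and supervised vigilance learning.

Fuzzy ART clusters inputs incrementally into hyperbox categories; the
vigilance rho sets the box size (higher rho -> more, smaller categories).
The supervised stage of the pipeline exploits this monotonicity: it lowers
rho from 1 until a supervising region's inputs form exactly one category.
"""

import numpy as np

from unitedcells import FuzzyArt, complement_code, learn_vigilance

rng = np.random.default_rng(0)
# two clouds in the unit square
inputs = np.vstack([
    rng.uniform(0.05, 0.25, size=(20, 2)),
    rng.uniform(0.65, 0.95, size=(20, 2)),
])
H = complement_code(inputs)
print(f"inputs: {inputs.shape[0]} points in [0,1]^2; |H| = {H[0].sum():.0f} = p")

for rho in (0.5, 0.8, 0.95):
    art = FuzzyArt(dim=2, alpha=0.001, beta=1.0, rho=rho)
    art.run(H)
    print(f"rho = {rho:.2f}: {art.n_categories} categories")

rho_one = learn_vigilance(complement_code(inputs[:20]))
print(
    f"vigilance learned for the first cloud alone: {rho_one:.3f} "
    "(largest rho at which it forms a single category)"
)
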