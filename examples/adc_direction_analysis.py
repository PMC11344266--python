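"""Per-direction ADC maps and the gradient-direction bias test.

The apparent diffusion coefficient, ADC = -ln(S/S0)/b, is computed per
gradient direction.  On a noiseless tensor phantom the ADC along
direction g equals the quadratic form gᵀDg of the local diffusion
tensor, so the white-matter swirl produces direction-dependent values
while isotropic compartments do not.  A Kruskal-Wallis rank test across
directions checks whether any direction is systematically favored.
"""

import numpy as np

from dwifov.evaluation import adc_map, direction_bias_test
from dwifov.phantom import PhantomSpec, generate_phantom

spec = PhantomSpec(sigma=0.0, structural_sigma=0.0, seed=11, n_weighted=6)
study, _, brain, tensors = generate_phantom(spec)
inside = brain.mask.astype(bool) & (study.data[..., 0] > 1e-6)

print(f"{'dir':>3} {'gx':>6} {'gy':>6} {'gz':>6}  {'mean ADC (white)':>18}")
white = inside & np.isclose(study.data[..., 0], 0.65, atol=0.01)
per_direction = []
for d, v in enumerate(study.gradients.weighted_indices):
    adc = adc_map(study, d)
    g = study.gradients.bvecs[v]
    expected = np.einsum("...ij,i,j->...", tensors, g, g)
    err = np.nanmax(np.abs(adc[inside] - expected[inside]))
    vals = adc[white]
    per_direction.append(vals[np.isfinite(vals)])
    print(f"{d:>3} {g[0]:6.2f} {g[1]:6.2f} {g[2]:6.2f} "
          f"{np.nanmean(vals):18.5e}   (|ADC - gᵀDg| ≤ {err:.1e})")

h, p = direction_bias_test([v[:200] for v in per_direction])
print(f"\nKruskal-Wallis across directions: H = {h:.2f}, p = {p:.3g}")
print("White-matter ADC varies across directions (anisotropy), so a "
      "significant H here reflects real tensor structure; on an "
      "imputation-error metric the same test checks for direction bias.")
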