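"""Simulate one DWI + T1w phantom and look at its tensor-model contrast.

Builds a 48-cubed nested-ellipsoid phantom (CSF rim / gray shell / white
core) with one b=0 volume and six b=1300 s/mm² directions, then prints
the mean signal per compartment.  High diffusivity along the encoding
direction attenuates the signal, so CSF — bright on the b0 image — is
nearly black on the diffusion-weighted volumes, while the T1w-like
structural channel shows the opposite ordering (white matter brightest).
"""

import numpy as np

from dwifov.phantom import PhantomSpec, generate_phantom

# bias field off so the table below shows pure compartment values
spec = PhantomSpec(seed=42, bias_field_amplitude=0.0)
study, structural, brain, tensors = generate_phantom(spec)

print(f"phantom grid {study.shape}, {study.n_volumes} volumes "
      f"({len(study.gradients.b0_indices)} b0 + "
      f"{len(study.gradients.weighted_indices)} weighted at "
      f"b={study.gradients.bvals.max():.0f} s/mm2)")

b0 = study.data[..., 0]
dwi = study.data[..., study.gradients.weighted_indices].mean(axis=3)
inside = brain.mask.astype(bool)

print(f"{'compartment':<12}{'b0':>8}{'mean DWI':>10}{'T1w':>8}")
for name, lo, hi in (("CSF", 0.9, 1.1), ("gray", 0.70, 0.80),
                     ("white", 0.60, 0.70)):
    sel = inside & (b0 > lo) & (b0 <= hi)
    print(f"{name:<12}{b0[sel].mean():>8.3f}{dwi[sel].mean():>10.3f}"
          f"{structural.data[sel].mean():>8.3f}")

print("\nCSF attenuates most under diffusion weighting (largest D), and "
      "the T1w contrast ordering is inverted relative to b0 — the two "
      "channels are correlated but not redundant.")
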