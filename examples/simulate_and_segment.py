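"""Render a skin phantom and segment the air-skin interface.

The classical backend finds, per A-scan, the strongest upward intensity step
(on log intensity, where speckle is additive) near an adaptive-threshold
crossing.  The score against the rendered ground-truth mask is the mean
intersection-over-union over the two classes.
"""

import numpy as np

from octskin import (
    PhantomSpec,
    extract_boundary,
    miou,
    render_volume,
    segment_volume_classical,
)

spec = PhantomSpec(n_slices=20, n_depth=256, n_lateral=256,
                   surface_profile="filtered-noise", amplitude=12.0,
                   curvature_coeff=1e-6, seed=3)
volume, truth = render_volume(spec)
mask = segment_volume_classical(volume)
score = miou(mask, truth.true_mask)

boundary = extract_boundary(mask, volume.axial_pitch)
err_rows = (-boundary.heights / volume.axial_pitch) - truth.surface_row

print(f"MIoU vs ground truth   : {score:.2f} / 100")
print(f"interpolated columns   : {100 * boundary.missing_fraction:.2f} %")
print(f"boundary error (rows)  : mean |e| = {np.abs(err_rows - err_rows.mean()).mean():.2f}, "
      f"max |e| = {np.abs(err_rows - err_rows.mean()).max():.2f}")
print("An MIoU near 100 with sub-pixel mean boundary error means the surface "
      "texture, not segmentation noise, dominates the roughness estimate.")
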