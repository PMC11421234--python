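"""Scanner-corruption models and their corrections.

Injects velocity aliasing (wrapping at venc = 160 cm/s) and a linear
eddy-current background phase into a phantom, then shows that the
preprocessing recovers the true field.
"""

import dataclasses

import numpy as np

from dissectflow import PhantomConfig, generate_phantom
from dissectflow.preprocess import correct_eddy_currents, unwrap_velocity

cfg = PhantomConfig(
    tl_radius=6.0, fl_radius=8.0, length=30.0, grid_spacing=2.0,
    n_timepoints=16, peak_tl_velocity=170.0, aliasing_enabled=True,
    venc=160.0, seed=4,
)
field, _, masks, truth = generate_phantom(cfg)
restored, n = unwrap_velocity(field)
exact = all(
    np.array_equal(a, b)
    for a, b in zip(restored.components, truth.true_field.components)
)
print(f"aliasing: {truth.wrap_count} voxel values wrapped at venc, "
      f"{n} corrected, bit-exact restoration: {exact}")

eddy = ((12.0, 0.4, -0.3, 0.2), (-8.0, -0.2, 0.5, 0.1), (5.0, 0.1, 0.2, -0.4))
cfg_e = dataclasses.replace(
    cfg, peak_tl_velocity=120.0, aliasing_enabled=False, eddy_coefficients=eddy
)
field_e, _, masks_e, _ = generate_phantom(cfg_e)
corrected, coeffs = correct_eddy_currents(field_e, masks_e.static_tissue)
err = np.abs(coeffs - np.asarray(eddy)).max()
print(f"eddy currents: injected linear background recovered with max "
      f"coefficient error {err:.1e} cm/s (least squares on "
      f"{int(masks_e.static_tissue.sum())} static voxels)")
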