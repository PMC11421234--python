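"""Viscous energy loss against the Hagen-Poiseuille dissipation identity.

For steady laminar pipe flow the viscous dissipation integrated over the
lumen equals the pumping power Q * dP = 8 mu L Q^2 / (pi R^4).  The voxel-wise
dissipation-function estimate should converge to it with grid refinement.
"""

import numpy as np

from dissectflow.core import VelocityField4D, VoxelGrid
from dissectflow.hemodynamics import compute_energy_loss

R, L, Q = 8.0, 60.0, 80.0  # mm, mm, mL/s
mu = 3.2e-3  # Pa s
analytic = 8.0 * mu * (L * 1e-3) * (Q * 1e-6) ** 2 / (np.pi * (R * 1e-3) ** 4)
print(f"analytic dissipation 8*mu*L*Q^2/(pi*R^4) = {analytic * 1e3:.3f} mW")

for h in (1.0, 0.5):
    half = R + 2.0
    n_xy = int(np.floor(2 * half / h)) + 1
    n_z = int(np.floor(L / h)) + 1
    grid = VoxelGrid((n_xy, n_xy, n_z), (h, h, h), (-half, -half, 0.0))
    xyz = grid.world_coordinates()
    r2 = xyz[..., 0] ** 2 + xyz[..., 1] ** 2
    mask = r2 <= R**2
    v_max = 2.0 * Q * 1e3 / (np.pi * R**2)  # mm/s
    vz = np.where(mask, v_max * (1.0 - r2 / R**2), 0.0) / 10.0  # cm/s
    zeros = np.zeros(grid.shape + (2,))
    field = VelocityField4D(
        vx=zeros.copy(), vy=zeros.copy(),
        vz=np.repeat(vz[..., None], 2, axis=3), grid=grid, venc=1e4,
        temporal_resolution=500.0, rr_interval=1000.0,
    )
    _, el_mean, _ = compute_energy_loss(field, mask)
    total = el_mean[mask].sum()
    print(f"h = {h} mm: {total * 1e3:.3f} mW "
          f"({100 * (total - analytic) / analytic:+.1f}% vs analytic)")
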