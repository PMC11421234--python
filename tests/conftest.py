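"""Shared fixtures: small clean phantoms and analytic field builders."""

from __future__ import annotations

import numpy as np
import pytest

from dissectflow.core import FluidConstants, VelocityField4D, VoxelGrid
from dissectflow.phantom import PhantomConfig, generate_phantom


@pytest.fixture(scope="session")
def clean_phantom():
    """Uncorrupted straight two-lumen phantom with a 0.3 retrograde fraction."""
    cfg = PhantomConfig(
        tl_radius=6.0, fl_radius=8.0, length=48.0, grid_spacing=1.5,
        n_timepoints=16, fl_retrograde_fraction=0.3, seed=7,
    )
    return cfg, generate_phantom(cfg)


def make_uniform_field(
    shape=(4, 4, 4), spacing=1.0, value=(0.0, 0.0, 10.0), n_t=4,
    venc=160.0, rr=1000.0,
) -> VelocityField4D:
    grid = VoxelGrid(shape, (spacing,) * 3)
    full = lambda v: np.full(shape + (n_t,), float(v))
    return VelocityField4D(
        vx=full(value[0]), vy=full(value[1]), vz=full(value[2]),
        grid=grid, venc=venc, temporal_resolution=rr / n_t, rr_interval=rr,
    )


def make_random_field(
    rng: np.random.Generator, shape=(5, 4, 3), n_t=4, scale=50.0,
    spacing=1.0, venc=160.0,
) -> VelocityField4D:
    grid = VoxelGrid(shape, (spacing,) * 3)
    draw = lambda: rng.normal(0.0, scale, size=shape + (n_t,))
    return VelocityField4D(
        vx=draw(), vy=draw(), vz=draw(), grid=grid, venc=venc,
        temporal_resolution=250.0, rr_interval=250.0 * n_t,
    )


def make_poiseuille_field(
    radius_mm: float = 8.0,
    length_mm: float = 60.0,
    flow_ml_s: float = 80.0,
    spacing_mm: float = 1.0,
    n_t: int = 2,
    margin_mm: float = 2.0,
):
    """Steady Poiseuille pipe along z; returns (field, lumen mask).

    Centerline velocity v_max = 2Q / (pi R^2); the analytic lumen-summed
    dissipation rate is 8 mu L Q^2 / (pi R^4).
    """
    h = spacing_mm
    half = radius_mm + margin_mm
    n_xy = int(np.floor(2 * half / h)) + 1
    n_z = int(np.floor(length_mm / h)) + 1
    grid = VoxelGrid((n_xy, n_xy, n_z), (h, h, h), (-half, -half, 0.0))
    xyz = grid.world_coordinates()
    r2 = xyz[..., 0] ** 2 + xyz[..., 1] ** 2
    mask = r2 <= radius_mm**2
    v_max_mm_s = 2.0 * flow_ml_s * 1e3 / (np.pi * radius_mm**2)  # mm/s
    vz = np.where(mask, v_max_mm_s * (1.0 - r2 / radius_mm**2), 0.0) / 10.0  # cm/s
    zeros = np.zeros(grid.shape + (n_t,))
    field = VelocityField4D(
        vx=zeros.copy(), vy=zeros.copy(),
        vz=np.repeat(vz[..., None], n_t, axis=3),
        grid=grid, venc=10000.0,
        temporal_resolution=1000.0 / n_t, rr_interval=1000.0,
    )
    return field, mask


def poiseuille_analytic_dissipation_w(
    radius_mm: float, length_mm: float, flow_ml_s: float,
    constants: FluidConstants = FluidConstants(),
) -> float:
    """8 mu L Q^2 / (pi R^4) in watts."""
    mu = constants.mu_pa_s
    L = length_mm * 1e-3
    Q = flow_ml_s * 1e-6
    R = radius_mm * 1e-3
    return 8.0 * mu * L * Q**2 / (np.pi * R**4)
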