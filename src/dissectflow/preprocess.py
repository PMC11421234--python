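"""Phase-contrast preprocessing chain.

Order of operations, fixed and deliberate: eddy-current correction ->
noise masking -> velocity anti-aliasing -> cardiac-cycle truncation ->
isotropic spline interpolation.  PC-MRA computation can run at any point
after anti-aliasing.

The eddy-current (background phase) model is a spatial polynomial of order
0 or 1 per velocity component, fit by least squares to the time-averaged
velocity of static-tissue voxels — the standard stationary-tissue correction
for phase-contrast data.  Anti-aliasing uses a temporal-jump detector that is
exactly invertible in the single-wrap regime; it performs no spatial
unwrapping.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core import LumenMasks, MagnitudeSeries, VelocityField4D, VoxelGrid

__all__ = [
    "PreprocessConfig",
    "PcmraVolume",
    "correct_eddy_currents",
    "apply_noise_mask",
    "unwrap_velocity",
    "compute_pcmra",
    "truncate_cycle",
    "interpolate_to_isotropic",
    "run_preprocessing",
]


@dataclass(frozen=True)
class PreprocessConfig:
    """Preprocessing parameters.

    ``cycle_cutoff_fraction`` is the fraction of the cardiac cycle retained in
    every scan so that prospectively triggered acquisitions (which omit late
    diastole) and retrospectively gated ones contribute the same cycle window;
    the default 0.673 is the minimum cycle coverage of a prospective scan in
    the cohort this pipeline was designed around.  ``noise_threshold`` is a
    fraction of the peak time-averaged magnitude below which voxels are
    treated as airspace.  ``target_spacing`` is the isotropic resampling
    resolution in mm.
    """

    cycle_cutoff_fraction: float = 0.673
    noise_threshold: float = 0.1
    eddy_polynomial_order: int = 1
    target_spacing: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 < self.cycle_cutoff_fraction <= 1.0:
            raise ValueError("cycle_cutoff_fraction must be in (0, 1]")
        if self.target_spacing <= 0:
            raise ValueError("target_spacing must be positive")
        if self.eddy_polynomial_order not in (0, 1):
            raise ValueError("eddy_polynomial_order must be 0 or 1")


@dataclass
class PcmraVolume:
    """Phase-contrast angiogram: time-mean of squared speed, (cm/s)^2."""

    values: np.ndarray
    grid: VoxelGrid

    def __post_init__(self) -> None:
        if np.any(self.values < 0):
            raise ValueError("PC-MRA values must be non-negative")

    def display(self, sqrt: bool = False) -> np.ndarray:
        """Values for display; ``sqrt=True`` returns root-mean-square speed."""
        return np.sqrt(self.values) if sqrt else self.values


def correct_eddy_currents(
    field: VelocityField4D,
    static_mask: np.ndarray,
    order: int = 1,
) -> tuple[VelocityField4D, np.ndarray]:
    """Subtract a fitted static-tissue background-phase offset per component.

    For each velocity component, a spatial polynomial (constant for
    ``order=0``, ``a + b*x + c*y + d*z`` in world mm for ``order=1``) is fit
    by least squares to the time-averaged velocity over static-tissue voxels,
    then subtracted from every voxel at every timepoint.

    Returns the corrected field and the fitted coefficients, shape (3, 4)
    with the order-0 fit leaving the linear terms zero.
    """
    static_mask = np.asarray(static_mask, dtype=bool)
    n_static = int(static_mask.sum())
    if n_static == 0:
        raise ValueError("static-tissue mask is empty; cannot fit eddy currents")
    if n_static < 10:
        raise ValueError(
            f"static-tissue mask has only {n_static} voxels; need >= 10 for a stable fit"
        )
    xyz = field.grid.world_coordinates()[static_mask]
    if order == 1:
        design = np.column_stack([np.ones(n_static), xyz])
        rank = np.linalg.matrix_rank(design)
        if rank < 4:
            warnings.warn(
                "static voxels are spatially degenerate (coplanar); "
                "falling back to order-0 eddy correction",
                stacklevel=2,
            )
            order = 0
    if order == 0:
        design = np.ones((n_static, 1))

    coeffs = np.zeros((3, 4))
    out = field.copy()
    grid_xyz = field.grid.world_coordinates()
    for i, comp in enumerate(out.components):
        tavg = comp.mean(axis=3)[static_mask]
        beta, *_ = np.linalg.lstsq(design, tavg, rcond=None)
        if order == 1:
            coeffs[i] = beta
        else:
            coeffs[i, 0] = beta[0]
        offset = (
            coeffs[i, 0]
            + coeffs[i, 1] * grid_xyz[..., 0]
            + coeffs[i, 2] * grid_xyz[..., 1]
            + coeffs[i, 3] * grid_xyz[..., 2]
        )
        comp -= offset[..., None]
    return out, coeffs


def apply_noise_mask(
    field: VelocityField4D,
    magnitude: MagnitudeSeries,
    threshold: float = 0.1,
) -> tuple[VelocityField4D, np.ndarray]:
    """Zero velocities where time-averaged magnitude falls below threshold.

    A voxel is masked when its time-averaged magnitude is strictly below
    ``threshold`` times the peak time-averaged magnitude.  Returns the masked
    field and the boolean mask of zeroed voxels.
    """
    if magnitude.magnitude.shape[:3] != field.vx.shape[:3]:
        raise ValueError("magnitude and velocity grids do not match")
    tavg = magnitude.time_averaged()
    noise_mask = tavg < threshold * tavg.max()
    out = field.copy()
    for comp in out.components:
        comp[noise_mask] = 0.0
    return out, noise_mask


def unwrap_velocity(field: VelocityField4D) -> tuple[VelocityField4D, int]:
    """Anti-aliasing by temporal continuity, exact in the single-wrap regime.

    Scanning each voxel's time series in order, a jump of more than venc
    relative to the previous (already corrected) frame is attributed to phase
    wrapping and removed by the nearest multiple of 2*venc.  This assumes the
    first frame is unaliased and true frame-to-frame velocity changes stay
    below venc — valid for aortic flow sampled at typical 4D-flow temporal
    resolution.  Returns the corrected field and the number of corrected
    scalar values.
    """
    venc = field.venc
    out = field.copy()
    n_corrected = 0
    for comp in out.components:
        for t in range(1, comp.shape[3]):
            jump = comp[..., t] - comp[..., t - 1]
            k = np.round(jump / (2.0 * venc))
            fix = np.abs(jump) > venc
            if np.any(fix):
                comp[..., t][fix] -= 2.0 * venc * k[fix]
                n_corrected += int(fix.sum())
    return out, n_corrected


def compute_pcmra(field: VelocityField4D) -> PcmraVolume:
    """PC angiogram: per-voxel time-mean of vx^2 + vy^2 + vz^2, (cm/s)^2."""
    sq = field.vx**2 + field.vy**2 + field.vz**2
    return PcmraVolume(values=sq.mean(axis=3), grid=field.grid)


def truncate_cycle(
    field: VelocityField4D, cutoff_fraction: float = 0.673
) -> VelocityField4D:
    """Retain the first floor(T_full * cutoff) frames of the cycle.

    ``T_full`` is the full-cycle frame count ``rr_interval /
    temporal_resolution``, so a retrospective full-cycle scan at cutoff 1.0 is
    returned unchanged, and all scans are cut to a common cycle window
    measured from early systole.  At least 2 frames are always retained.
    """
    if not 0.0 < cutoff_fraction <= 1.0:
        raise ValueError("cutoff_fraction must be in (0, 1]")
    t_full = field.rr_interval / field.temporal_resolution
    keep = int(np.floor(t_full * cutoff_fraction))
    keep = max(keep, 2)
    keep = min(keep, field.n_timepoints)
    return dataclasses.replace(
        field,
        vx=field.vx[..., :keep].copy(),
        vy=field.vy[..., :keep].copy(),
        vz=field.vz[..., :keep].copy(),
    )


def _resampled_grid(grid: VoxelGrid, target: float) -> VoxelGrid:
    shape = tuple(
        int(np.floor((grid.shape[a] - 1) * grid.spacing[a] / target)) + 1
        for a in range(3)
    )
    return VoxelGrid(shape=shape, spacing=(target,) * 3, origin=grid.origin)


def interpolate_to_isotropic(
    field: VelocityField4D,
    masks: LumenMasks | None,
    target_spacing: float = 1.0,
) -> tuple[VelocityField4D, LumenMasks | None]:
    """Cubic-spline resample each component/timepoint onto an isotropic grid.

    Masks are resampled by nearest neighbor.  Interpolation is spatial only;
    the time axis is untouched.  The target grid shares the source origin and
    covers the same extent, so source voxel centers that coincide with target
    centers reproduce their values (splines interpolate their knots).
    """
    grid = field.grid
    if target_spacing > min(grid.spacing) + 1e-9:
        raise ValueError(
            f"target spacing {target_spacing} mm is coarser than the source "
            f"grid {grid.spacing}; refusing to downsample"
        )
    new_grid = _resampled_grid(grid, target_spacing)
    # fractional source-index coordinates of target voxel centers
    idx = [
        np.arange(new_grid.shape[a]) * target_spacing / grid.spacing[a]
        for a in range(3)
    ]
    ii, jj, kk = np.meshgrid(*idx, indexing="ij")
    coords = np.stack([ii, jj, kk])

    T = field.n_timepoints
    comps = []
    for comp in field.components:
        new = np.empty(new_grid.shape + (T,))
        for t in range(T):
            new[..., t] = ndimage.map_coordinates(
                comp[..., t], coords, order=3, mode="mirror"
            )
        comps.append(new)
    new_field = dataclasses.replace(
        field, vx=comps[0], vy=comps[1], vz=comps[2], grid=new_grid
    )

    new_masks = None
    if masks is not None:
        def resample_mask(m: np.ndarray) -> np.ndarray:
            return (
                ndimage.map_coordinates(
                    m.astype(np.float32), coords, order=0, mode="nearest"
                )
                > 0.5
            )

        tl = resample_mask(masks.tl)
        fl = resample_mask(masks.fl) & ~tl
        new_masks = LumenMasks(
            whole=tl | fl,
            tl=tl,
            fl=fl,
            static_tissue=resample_mask(masks.static_tissue) & ~(tl | fl),
        )
    return new_field, new_masks


def run_preprocessing(
    field: VelocityField4D,
    magnitude: MagnitudeSeries,
    masks: LumenMasks,
    config: PreprocessConfig = PreprocessConfig(),
) -> tuple[VelocityField4D, LumenMasks, PcmraVolume, dict]:
    """Full chain: eddy correction, noise mask, unwrap, truncate, interpolate.

    Returns the preprocessed field and masks on the isotropic grid, the
    PC-MRA (computed on the corrected, unwrapped, full-cycle field), and a
    dict of diagnostics (eddy coefficients, unwrap count, noise-mask size).
    """
    field, eddy_coeffs = correct_eddy_currents(
        field, masks.static_tissue, order=config.eddy_polynomial_order
    )
    field, noise_mask = apply_noise_mask(field, magnitude, config.noise_threshold)
    field, n_unwrapped = unwrap_velocity(field)
    pcmra = compute_pcmra(field)
    field = truncate_cycle(field, config.cycle_cutoff_fraction)
    field, masks = interpolate_to_isotropic(field, masks, config.target_spacing)
    info = {
        "eddy_coefficients": eddy_coeffs,
        "n_unwrapped": n_unwrapped,
        "n_noise_masked": int(noise_mask.sum()),
    }
    return field, masks, pcmra, info
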