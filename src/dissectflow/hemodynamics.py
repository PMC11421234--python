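"""Voxel-wise hemodynamic maps and luminal summaries.

All quantities follow the 4D-flow literature conventions for dissection
analysis:

* Kinetic energy per voxel, ``KE(t) = 0.5 * rho * dV * |v(t)|^2``, summed over
  the retained cardiac cycle and reported as the sum over the luminal volume
  in joules.
* Forward / reverse flow: the through-plane velocity relative to the matched
  centerline plane's normal, integrated over the cycle per voxel (mL/cycle),
  reported as the mean over the luminal volume.
* Maximum velocity (MV): at the timepoint with the highest 95th-percentile
  voxel speed (chosen independently per lumen), the mean of the top 5% of
  voxel speeds, in m/s.
* Viscous energy loss: the Newtonian viscous dissipation function

      phi_v = 1/2 * sum_ij [ d(v_j)/d(x_i) + d(v_i)/d(x_j)
                              - 2/3 * div(v) * delta_ij ]^2

  (units s^-2), multiplied by viscosity and voxel volume to give a per-voxel
  dissipation rate in watts, integrated over the cycle (EL_total, J) and
  time-averaged (EL_mean, W).  Spatial derivatives use central differences
  restricted to in-lumen neighbors, falling back to one-sided differences at
  the wall, so the zeroed background never induces artificial shear.

Internally everything is converted to SI; presentation units are J, m/s,
mL/cycle and W.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .core import FluidConstants, LumenMasks, VelocityField4D
from .geometry import (
    FL_DISTAL,
    FL_PROXIMAL,
    TL_DISTAL,
    TL_PROXIMAL,
    RegionLabels,
    VoxelPlaneAssignment,
)

__all__ = [
    "HemodynamicMaps",
    "LuminalSummary",
    "compute_kinetic_energy",
    "compute_flow_decomposition",
    "compute_max_velocity",
    "compute_energy_loss",
    "compute_maps",
    "summarize_lumen",
]

CM_S_TO_M_S = 1e-2
MM3_TO_M3 = 1e-9
MM2_TO_M2 = 1e-6
MS_TO_S = 1e-3
M3_TO_ML = 1e6


@dataclass
class HemodynamicMaps:
    """Per-voxel maps on the analysis grid (zero outside the lumen)."""

    ke: np.ndarray  # J, summed over retained cycle
    ff: np.ndarray  # mL/cycle
    rf: np.ndarray  # mL/cycle
    mv_map_tl: np.ndarray  # m/s speed at the TL's selected timepoint
    mv_map_fl: np.ndarray  # m/s speed at the FL's selected timepoint
    el_total: np.ndarray  # J
    el_rate_mean: np.ndarray  # W
    mv_timepoint_tl: int = 0
    mv_timepoint_fl: int = 0
    phi_v: np.ndarray | None = None  # s^-2, optional 4D debug output


@dataclass
class LuminalSummary:
    """The six headline scalars plus regional and energy-loss summaries.

    Units match conventional reporting: KE in J (sum over lumen and cycle),
    MV in m/s, FF/RF in mL/cycle (mean over lumen), EL_total in J and
    EL_mean in W (means over the region's voxels).
    """

    tl_ke: float
    tl_mv: float
    tl_ff: float
    fl_ke: float
    fl_mv: float
    fl_rf: float
    fl_ff: float = float("nan")
    el_total_fl: float = float("nan")
    el_mean_fl: float = float("nan")
    el_total_dao: float = float("nan")
    el_mean_dao: float = float("nan")
    regional: dict = field(default_factory=dict)

    def to_row(self) -> dict:
        row = {
            "tl_ke": self.tl_ke, "tl_mv": self.tl_mv, "tl_ff": self.tl_ff,
            "fl_ke": self.fl_ke, "fl_mv": self.fl_mv, "fl_rf": self.fl_rf,
            "fl_ff": self.fl_ff,
            "el_total_fl": self.el_total_fl, "el_mean_fl": self.el_mean_fl,
            "el_total_dao": self.el_total_dao, "el_mean_dao": self.el_mean_dao,
        }
        row.update(self.regional)
        return row

    PARAMETERS = ("tl_ke", "tl_mv", "tl_ff", "fl_ke", "fl_mv", "fl_rf")


def compute_kinetic_energy(
    field: VelocityField4D,
    mask: np.ndarray,
    constants: FluidConstants = FluidConstants(),
) -> tuple[np.ndarray, float]:
    """Per-voxel cycle-summed KE map (J) and the mask-summed total (J)."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask: no voxels to integrate KE over")
    dv = field.grid.voxel_volume * MM3_TO_M3
    speed_sq = (
        (field.vx * CM_S_TO_M_S) ** 2
        + (field.vy * CM_S_TO_M_S) ** 2
        + (field.vz * CM_S_TO_M_S) ** 2
    )
    ke_map = 0.5 * constants.rho * dv * speed_sq.sum(axis=3)
    ke_map = np.where(mask, ke_map, 0.0)
    return ke_map, float(ke_map[mask].sum())


def compute_flow_decomposition(
    field: VelocityField4D,
    assignment: VoxelPlaneAssignment,
    masks: LumenMasks,
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Per-voxel forward/reverse flow maps (mL/cycle) and lumen means.

    The through-plane velocity is the projection of the voxel's velocity onto
    its matched plane's normal; positive projections integrate into forward
    flow, negative into reverse flow, each weighted by the voxel cross-section
    ``spacing^2`` and the frame duration.  Returns (ff_map, rf_map, means)
    where means holds ``tl_ff``, ``tl_rf``, ``fl_ff``, ``fl_rf``.
    """
    grid = field.grid
    if not grid.is_isotropic:
        raise ValueError("flow decomposition requires an isotropic grid; interpolate first")
    ii = assignment.voxel_indices
    n_lum = len(assignment.plane_index)
    if n_lum != int(masks.whole.sum()):
        raise ValueError("plane assignment does not cover the luminal mask")
    v = np.stack(
        [comp[ii] for comp in field.components], axis=1
    )  # (n_lum, 3, T), cm/s
    s = np.einsum("nct,nc->nt", v, assignment.forward_direction) * CM_S_TO_M_S
    area = grid.spacing[0] ** 2 * MM2_TO_M2
    dt = field.temporal_resolution * MS_TO_S
    ff_vox = np.maximum(s, 0.0).sum(axis=1) * area * dt * M3_TO_ML
    rf_vox = np.maximum(-s, 0.0).sum(axis=1) * area * dt * M3_TO_ML

    ff_map = np.zeros(masks.whole.shape)
    rf_map = np.zeros(masks.whole.shape)
    ff_map[ii] = ff_vox
    rf_map[ii] = rf_vox
    is_tl = masks.tl[ii]
    is_fl = masks.fl[ii]
    means = {
        "tl_ff": float(ff_vox[is_tl].mean()) if is_tl.any() else float("nan"),
        "tl_rf": float(rf_vox[is_tl].mean()) if is_tl.any() else float("nan"),
        "fl_ff": float(ff_vox[is_fl].mean()) if is_fl.any() else float("nan"),
        "fl_rf": float(rf_vox[is_fl].mean()) if is_fl.any() else float("nan"),
    }
    return ff_map, rf_map, means


def compute_max_velocity(
    field: VelocityField4D, mask: np.ndarray
) -> tuple[float, int, np.ndarray]:
    """MV scalar (m/s), selected timepoint, and the speed map at it.

    The timepoint maximizing the 95th percentile of voxel speeds inside the
    mask is selected (earliest on ties); MV is the mean of speeds at or above
    that percentile at the selected timepoint.  Masks smaller than 20 voxels
    make the top-5% ill-defined: a warning is raised and the plain maximum is
    used.
    """
    mask = np.asarray(mask, dtype=bool)
    n = int(mask.sum())
    if n == 0:
        raise ValueError("empty mask: MV undefined")
    speeds = field.speed()[mask] * CM_S_TO_M_S  # (n, T)
    if n < 20:
        warnings.warn(
            f"mask has only {n} voxels; top-5% MV ill-defined, using the maximum",
            stacklevel=2,
        )
        per_t = speeds.max(axis=0)
        t_star = int(np.argmax(per_t))
        mv = float(per_t[t_star])
    else:
        p95 = np.percentile(speeds, 95.0, axis=0)
        t_star = int(np.argmax(p95))
        at_t = speeds[:, t_star]
        mv = float(at_t[at_t >= p95[t_star]].mean())
    mv_map = np.zeros(mask.shape)
    mv_map[mask] = speeds[:, t_star]
    return mv, t_star, mv_map


def _masked_gradient(f: np.ndarray, mask: np.ndarray, axis: int, h: float) -> np.ndarray:
    """d(f)/d(axis) inside ``mask`` using only in-mask neighbors.

    Central difference where both neighbors are in the mask, one-sided where
    one is, zero where the voxel is isolated along the axis.  ``h`` in meters.
    """
    fp = np.roll(f, -1, axis=axis)
    fm = np.roll(f, 1, axis=axis)
    mp = np.roll(mask, -1, axis=axis)
    mm = np.roll(mask, 1, axis=axis)
    # roll wraps around; kill the wrapped faces
    sl_last = [slice(None)] * f.ndim
    sl_last[axis] = -1
    sl_first = [slice(None)] * f.ndim
    sl_first[axis] = 0
    mp = mp.copy()
    mm = mm.copy()
    mp[tuple(sl_last)] = False
    mm[tuple(sl_first)] = False

    grad = np.zeros_like(f)
    both = mp & mm
    only_p = mp & ~mm
    only_m = ~mp & mm
    grad[both] = (fp[both] - fm[both]) / (2.0 * h)
    grad[only_p] = (fp[only_p] - f[only_p]) / h
    grad[only_m] = (f[only_m] - fm[only_m]) / h
    grad[~mask] = 0.0
    return grad


def compute_energy_loss(
    field: VelocityField4D,
    mask: np.ndarray,
    constants: FluidConstants = FluidConstants(),
    keep_phi_v: bool = False,
) -> tuple[np.ndarray, np.ndarray, np.ndarray | None]:
    """Viscous dissipation maps over ``mask``.

    Returns ``(el_total, el_rate_mean, phi_v)``: per-voxel cycle-integrated
    energy loss (J), time-averaged dissipation rate (W), and optionally the
    raw dissipation function (s^-2, 4D).  Requires an isotropic grid so the
    finite-difference stencil is uniform.
    """
    grid = field.grid
    if not grid.is_isotropic:
        raise ValueError(
            "energy loss requires an isotropic grid; run interpolate_to_isotropic first"
        )
    mask = np.asarray(mask, dtype=bool)
    h = grid.spacing[0] * 1e-3  # m
    T = field.n_timepoints
    dt = field.temporal_resolution * MS_TO_S
    dv = grid.voxel_volume * MM3_TO_M3

    phi = np.zeros(mask.shape + (T,)) if keep_phi_v else None
    el_rate_sum = np.zeros(mask.shape)
    for t in range(T):
        comps = [c[..., t] * CM_S_TO_M_S for c in field.components]
        grads = np.empty((3, 3) + mask.shape)
        for j in range(3):  # component
            for i in range(3):  # direction
                grads[i, j] = _masked_gradient(comps[j], mask, axis=i, h=h)
        div = grads[0, 0] + grads[1, 1] + grads[2, 2]
        phi_t = np.zeros(mask.shape)
        for i in range(3):
            for j in range(3):
                term = grads[i, j] + grads[j, i]
                if i == j:
                    term = term - (2.0 / 3.0) * div
                phi_t += term**2
        phi_t *= 0.5
        phi_t[~mask] = 0.0
        el_rate_sum += phi_t
        if keep_phi_v:
            phi[..., t] = phi_t
    el_rate_mean = constants.mu_pa_s * dv * el_rate_sum / T
    el_total = constants.mu_pa_s * dv * el_rate_sum * dt
    return el_total, el_rate_mean, phi


def compute_maps(
    field: VelocityField4D,
    masks: LumenMasks,
    assignment: VoxelPlaneAssignment,
    constants: FluidConstants = FluidConstants(),
    keep_phi_v: bool = False,
) -> tuple[HemodynamicMaps, dict]:
    """All voxel-wise maps in one pass; returns (maps, flow means)."""
    ke_map, _ = compute_kinetic_energy(field, masks.whole, constants)
    ff_map, rf_map, flow_means = compute_flow_decomposition(field, assignment, masks)
    _, t_tl, mv_map_tl = compute_max_velocity(field, masks.tl)
    if masks.fl.any():
        _, t_fl, mv_map_fl = compute_max_velocity(field, masks.fl)
    else:
        t_fl, mv_map_fl = 0, np.zeros(masks.whole.shape)
    el_total, el_rate_mean, phi = compute_energy_loss(
        field, masks.whole, constants, keep_phi_v=keep_phi_v
    )
    maps = HemodynamicMaps(
        ke=ke_map, ff=ff_map, rf=rf_map,
        mv_map_tl=mv_map_tl, mv_map_fl=mv_map_fl,
        el_total=el_total, el_rate_mean=el_rate_mean,
        mv_timepoint_tl=t_tl, mv_timepoint_fl=t_fl,
        phi_v=phi,
    )
    return maps, flow_means


def summarize_lumen(
    field: VelocityField4D,
    masks: LumenMasks,
    assignment: VoxelPlaneAssignment,
    regions: RegionLabels | None = None,
    constants: FluidConstants = FluidConstants(),
) -> LuminalSummary:
    """Compute the six headline scalars and regional/EL summaries for a scan.

    KE is summed over the lumen, MV is the top-5% rule per lumen, FF/RF are
    luminal-mean per-voxel cycle volumes.  Regional entries (``ke_tl_prox``,
    ``ff_tl_dist``, ...) repeat the same definitions over the proximal/distal
    TL and FL regions when region labels are supplied; EL summaries are means
    over the FL and the combined descending aorta.
    """
    _, tl_ke = compute_kinetic_energy(field, masks.tl, constants)
    fl_ke = float("nan")
    if masks.fl.any():
        _, fl_ke = compute_kinetic_energy(field, masks.fl, constants)
    tl_mv, _, _ = compute_max_velocity(field, masks.tl)
    fl_mv = float("nan")
    if masks.fl.any():
        fl_mv, _, _ = compute_max_velocity(field, masks.fl)
    ff_map, rf_map, flow_means = compute_flow_decomposition(field, assignment, masks)

    summary = LuminalSummary(
        tl_ke=tl_ke, tl_mv=tl_mv, tl_ff=flow_means["tl_ff"],
        fl_ke=fl_ke, fl_mv=fl_mv, fl_rf=flow_means["fl_rf"],
        fl_ff=flow_means["fl_ff"],
    )

    el_total, el_rate_mean, _ = compute_energy_loss(
        field, masks.whole, constants
    )
    if masks.fl.any():
        summary.el_total_fl = float(el_total[masks.fl].mean())
        summary.el_mean_fl = float(el_rate_mean[masks.fl].mean())
    if regions is not None:
        dao = regions.combined_dao
        if dao.any():
            summary.el_total_dao = float(el_total[dao].mean())
            summary.el_mean_dao = float(el_rate_mean[dao].mean())
        ke_map, _ = compute_kinetic_energy(field, masks.whole, constants)
        region_codes = {
            "tl_prox": TL_PROXIMAL, "tl_dist": TL_DISTAL,
            "fl_prox": FL_PROXIMAL, "fl_dist": FL_DISTAL,
        }
        for name, code in region_codes.items():
            rmask = regions.mask(code)
            if not rmask.any():
                continue
            summary.regional[f"ke_{name}"] = float(ke_map[rmask].sum())
            summary.regional[f"ff_{name}"] = float(ff_map[rmask].mean())
            summary.regional[f"rf_{name}"] = float(rf_map[rmask].mean())
            mv_r, _, _ = compute_max_velocity(field, rmask)
            summary.regional[f"mv_{name}"] = mv_r
    return summary
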