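"""Synthetic dissected-aorta 4D-flow phantom.

Builds an analytic two-lumen vessel (true lumen and false lumen separated by
an intimal-flap septum) on a regular voxel grid, prescribes pulsatile
near-parabolic axial flow in each lumen plus a cross-septum entry-tear jet,
and optionally applies scanner-style corruptions in image space:

* additive Gaussian velocity noise,
* a spatially linear eddy-current (background-phase) offset, constant in time,
* single-wrap velocity aliasing at the venc.

The fields are analytic prescriptions, not Navier-Stokes solutions: the point
is known ground truth for every downstream processing stage, not fluid
realism.  The geometry is either a straight segment or a circular arc
(a crude aortic arch); each lumen is a circular tube offset from the shared
centerline along the septum normal.

Everything is deterministic given the config seed: one integer seed feeds a
``numpy.random.SeedSequence`` whose spawned children drive each stochastic
component independently.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .core import LumenMasks, MagnitudeSeries, VelocityField4D, VoxelGrid

__all__ = [
    "PhantomConfig",
    "PhantomGroundTruth",
    "generate_phantom",
    "inject_aliasing",
    "inject_eddy_offset",
    "inject_noise",
    "tl_waveform",
    "fl_waveform",
]


def _raised_cosine(phase: np.ndarray, start: float, width: float) -> np.ndarray:
    """Single raised-cosine lobe on cycle phase in [0, 1); zero elsewhere."""
    u = (phase - start) / width
    lobe = 0.5 * (1.0 - np.cos(2.0 * np.pi * u))
    return np.where((u >= 0.0) & (u <= 1.0), lobe, 0.0)


def tl_waveform(phase: np.ndarray, peak_velocity: float) -> np.ndarray:
    """True-lumen centerline velocity (cm/s) over cycle phase in [0, 1).

    Sum of two raised cosines: a dominant systolic lobe peaking at
    ``peak_velocity`` and a small late-diastolic lobe, giving the forward
    pulsatile structure of aortic flow without a full Womersley solution.
    """
    phase = np.asarray(phase, dtype=float)
    return peak_velocity * (
        _raised_cosine(phase, 0.05, 0.30) + 0.12 * _raised_cosine(phase, 0.45, 0.35)
    )


def fl_waveform(
    phase: np.ndarray,
    peak_velocity: float,
    retrograde_fraction: float,
) -> np.ndarray:
    """False-lumen centerline velocity (cm/s) over cycle phase in [0, 1).

    A delayed forward systolic lobe plus a negative lobe starting in late
    systole and extending into diastole (FL flow lags the TL and reverses as
    the pressurized false lumen empties through tears).  The negative-lobe
    amplitude is scaled so that, sampled at the phases given, the retrograde
    volume fraction sum(max(-w,0)) / sum(|w|) equals ``retrograde_fraction``
    exactly.  With ``retrograde_fraction == 0`` the waveform is non-negative
    everywhere.
    """
    phase = np.asarray(phase, dtype=float)
    fwd = _raised_cosine(phase, 0.08, 0.26)
    rev = _raised_cosine(phase, 0.36, 0.34)
    if retrograde_fraction == 0.0:
        return peak_velocity * fwd
    s_fwd = float(fwd.sum())
    s_rev = float(rev.sum())
    if s_rev == 0.0 or s_fwd == 0.0:
        raise ValueError(
            "too few timepoints to realize a retrograde lobe; increase n_timepoints"
        )
    # amplitude solving  a*s_rev / (s_fwd + a*s_rev) = f  (lobes are disjoint)
    f = retrograde_fraction
    a = f * s_fwd / ((1.0 - f) * s_rev)
    return peak_velocity * (fwd - a * rev)


@dataclass(frozen=True)
class PhantomConfig:
    """Geometry, waveform, grid and corruption parameters of the phantom.

    Lengths in mm, velocities in cm/s, times in ms unless noted.  Defaults
    describe a chronic type-B dissection of the descending aorta: an ~40 mm
    total vessel diameter split into a smaller true lumen and a larger false
    lumen, peak TL velocity near systolic aortic values, a slower FL with a
    retrograde diastolic component, and a proximal entry tear.
    """

    tl_radius: float = 8.0
    fl_radius: float = 12.0
    septum_thickness: float = 1.0
    geometry: str = "straight"  # "straight" | "arched"
    arc_radius: float = 60.0
    length: float = 120.0
    septum_angle_deg: float = 0.0
    tear_fraction: float = 0.25  # arc-length fraction of tear center
    tear_radius: float = 5.0
    tear_jet_velocity: float = 80.0  # peak cross-septum jet speed, cm/s
    heart_rate: float = 70.0  # bpm
    peak_tl_velocity: float = 120.0
    peak_fl_velocity: float = 40.0
    fl_retrograde_fraction: float = 0.3
    n_timepoints: int = 16
    grid_spacing: float = 2.0
    static_tissue_thickness: float = 6.0
    air_margin: float = 4.0
    noise_snr: float | None = None  # None disables noise
    eddy_coefficients: tuple[tuple[float, float, float, float], ...] | None = None
    aliasing_enabled: bool = False
    venc: float = 160.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tl_radius <= 0 or self.fl_radius <= 0:
            raise ValueError("lumen radii must be positive")
        if not 0.0 <= self.fl_retrograde_fraction <= 1.0:
            raise ValueError("fl_retrograde_fraction must be in [0, 1]")
        if self.n_timepoints < 2:
            raise ValueError("need at least 2 timepoints")
        if self.geometry not in ("straight", "arched"):
            raise ValueError(f"unknown geometry {self.geometry!r}")

    @property
    def rr_interval_ms(self) -> float:
        return 60000.0 / self.heart_rate

    @property
    def temporal_resolution_ms(self) -> float:
        return self.rr_interval_ms / self.n_timepoints


@dataclass
class PhantomGroundTruth:
    """Pre-corruption truth emitted alongside the phantom dataset."""

    true_field: VelocityField4D
    true_masks: LumenMasks
    tl_flow_waveform: np.ndarray  # mL/s per timepoint
    fl_flow_waveform: np.ndarray  # mL/s per timepoint
    wrap_count: int
    eddy_coefficients: tuple[tuple[float, float, float, float], ...] | None


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------


def _lumen_offsets(cfg: PhantomConfig) -> tuple[float, float]:
    """Distances of TL / FL tube axes from the shared centerline."""
    half_septum = cfg.septum_thickness / 2.0
    return cfg.tl_radius + half_septum, cfg.fl_radius + half_septum


def _build_grid(cfg: PhantomConfig) -> VoxelGrid:
    d_tl, d_fl = _lumen_offsets(cfg)
    r_out = max(d_tl + cfg.tl_radius, d_fl + cfg.fl_radius)
    pad = r_out + cfg.static_tissue_thickness + cfg.air_margin
    h = cfg.grid_spacing
    if cfg.geometry == "straight":
        lo = np.array([-pad, -pad, 0.0])
        hi = np.array([pad, pad, cfg.length])
    else:
        # arc in the x-z plane centered at (arc_radius, 0, 0)
        theta_max = cfg.length / cfg.arc_radius
        th = np.linspace(0.0, theta_max, 200)
        cx = cfg.arc_radius * (1.0 - np.cos(th))
        cz = cfg.arc_radius * np.sin(th)
        lo = np.array([cx.min() - pad, -pad, cz.min() - pad])
        hi = np.array([cx.max() + pad, pad, cz.max() + pad])
    shape = tuple(int(np.floor((hi[a] - lo[a]) / h)) + 1 for a in range(3))
    return VoxelGrid(shape=shape, spacing=(h, h, h), origin=tuple(lo))


def _axis_geometry(cfg: PhantomConfig, pts: np.ndarray):
    """Per-point distance to each lumen axis, arc length, tangent and septum normal.

    ``pts``: (N, 3) world mm.  Returns dict with 'dist_tl', 'dist_fl',
    's' (arc length along the shared centerline, clipped to [0, length]),
    'tangent' (N, 3) and 'septum_normal' (N, 3) pointing TL -> FL.
    """
    d_tl, d_fl = _lumen_offsets(cfg)
    phi = np.deg2rad(cfg.septum_angle_deg)
    if cfg.geometry == "straight":
        e1 = np.array([np.cos(phi), np.sin(phi), 0.0])
        s = np.clip(pts[:, 2], 0.0, cfg.length)
        tangent = np.broadcast_to(np.array([0.0, 0.0, 1.0]), pts.shape)
        septum_normal = np.broadcast_to(e1, pts.shape)
        in_z = (pts[:, 2] >= 0.0) & (pts[:, 2] <= cfg.length)
        xy = pts[:, :2]
        c_tl = -d_tl * e1[:2]
        c_fl = d_fl * e1[:2]
        dist_tl = np.linalg.norm(xy - c_tl, axis=1)
        dist_fl = np.linalg.norm(xy - c_fl, axis=1)
        # points beyond the tube ends belong to no lumen
        dist_tl = np.where(in_z, dist_tl, np.inf)
        dist_fl = np.where(in_z, dist_fl, np.inf)
        center = np.stack(
            [np.zeros_like(s), np.zeros_like(s), s], axis=1
        )
        return dict(
            dist_tl=dist_tl, dist_fl=dist_fl, s=s,
            tangent=tangent, septum_normal=septum_normal, center=center,
        )
    # arched: shared centerline is an arc of radius Rc in the x-z plane,
    # centered at (Rc, 0, 0); the in-plane septum normal is the outward radial
    # direction rotated by the septum angle toward +y.
    rc = cfg.arc_radius
    theta_max = cfg.length / rc
    theta = np.arctan2(pts[:, 2], rc - pts[:, 0])
    theta_c = np.clip(theta, 0.0, theta_max)
    in_arc = (theta >= 0.0) & (theta <= theta_max)
    s = rc * theta_c
    cos_t, sin_t = np.cos(theta_c), np.sin(theta_c)
    # outward radial unit vector (away from the arc center)
    radial = np.stack([-cos_t, np.zeros_like(cos_t), sin_t], axis=1)
    tangent = np.stack([sin_t, np.zeros_like(cos_t), cos_t], axis=1)
    e1 = np.cos(phi) * radial
    e1[:, 1] += np.sin(phi)
    septum_normal = e1
    arc_center = np.array([rc, 0.0, 0.0])
    center = arc_center + rc * radial
    axis_tl = center - d_tl * septum_normal
    axis_fl = center + d_fl * septum_normal
    dist_tl = np.linalg.norm(pts - axis_tl, axis=1)
    dist_fl = np.linalg.norm(pts - axis_fl, axis=1)
    dist_tl = np.where(in_arc, dist_tl, np.inf)
    dist_fl = np.where(in_arc, dist_fl, np.inf)
    return dict(
        dist_tl=dist_tl, dist_fl=dist_fl, s=s,
        tangent=tangent, septum_normal=septum_normal, center=center,
    )


# ---------------------------------------------------------------------------
# corruption models
# ---------------------------------------------------------------------------


def inject_noise(field: VelocityField4D, snr: float, reference_velocity: float,
                 rng: np.random.Generator) -> VelocityField4D:
    """Add i.i.d. Gaussian noise of sigma = reference_velocity / snr (cm/s)."""
    sigma = reference_velocity / snr
    out = field.copy()
    out.vx += rng.normal(0.0, sigma, size=out.vx.shape)
    out.vy += rng.normal(0.0, sigma, size=out.vy.shape)
    out.vz += rng.normal(0.0, sigma, size=out.vz.shape)
    return out


def inject_eddy_offset(
    field: VelocityField4D,
    coefficients: tuple[tuple[float, float, float, float], ...],
) -> VelocityField4D:
    """Add a static background-phase offset ``a + b*x + c*y + d*z`` per component.

    Coordinates are world mm; the offset is constant over the cardiac cycle,
    the standard first-order model of residual eddy-current phase errors.
    """
    coeffs = np.asarray(coefficients, dtype=float)
    if coeffs.shape != (3, 4) or not np.all(np.isfinite(coeffs)):
        raise ValueError("expected finite coefficients of shape (3, 4)")
    xyz = field.grid.world_coordinates()
    out = field.copy()
    for comp, (a, b, c, d) in zip((out.vx, out.vy, out.vz), coeffs):
        offset = a + b * xyz[..., 0] + c * xyz[..., 1] + d * xyz[..., 2]
        comp += offset[..., None]
    return out


def inject_aliasing(field: VelocityField4D) -> tuple[VelocityField4D, int]:
    """Wrap velocities beyond +/-venc once: v -> v - 2*venc*sign(v).

    Valid in the single-wrap regime |v| < 3*venc (enforced).  Returns the
    corrupted field and the number of wrapped scalar values.
    """
    venc = field.venc
    out = field.copy()
    count = 0
    for comp in out.components:
        if np.any(np.abs(comp) >= 3.0 * venc):
            raise ValueError("velocities beyond 3*venc: outside single-wrap regime")
        wrapped = np.abs(comp) > venc
        comp[wrapped] -= 2.0 * venc * np.sign(comp[wrapped])
        count += int(wrapped.sum())
    return out, count


# ---------------------------------------------------------------------------
# phantom generation
# ---------------------------------------------------------------------------


def generate_phantom(
    cfg: PhantomConfig,
) -> tuple[VelocityField4D, MagnitudeSeries, LumenMasks, PhantomGroundTruth]:
    """Generate one synthetic 4D-flow scan with ground truth.

    Returns the (possibly corrupted) velocity field, a magnitude series, the
    true lumen masks, and a :class:`PhantomGroundTruth` holding the
    pre-corruption field and analytic per-lumen flow waveforms.

    Corruptions are applied in the order noise -> eddy offset -> wrapping,
    mirroring how they arise physically (thermal noise in the measurement,
    background phase added in reconstruction, phase wrapping at readout).
    """
    h = cfg.grid_spacing
    if min(cfg.tl_radius, cfg.fl_radius) / h < 3.0:
        raise ValueError(
            f"grid spacing {h} mm too coarse: need >= 3 voxels across the "
            f"smallest lumen radius {min(cfg.tl_radius, cfg.fl_radius)} mm"
        )
    grid = _build_grid(cfg)
    pts = grid.world_coordinates().reshape(-1, 3)
    geo = _axis_geometry(cfg, pts)

    tl = geo["dist_tl"] <= cfg.tl_radius
    fl = (geo["dist_fl"] <= cfg.fl_radius) & ~tl
    whole = tl | fl
    # static tissue: a sleeve around the vessel wall
    dist_wall = np.minimum(
        geo["dist_tl"] - cfg.tl_radius, geo["dist_fl"] - cfg.fl_radius
    )
    near = np.isfinite(dist_wall)
    static = (
        near & ~whole
        & (dist_wall > cfg.septum_thickness)
        & (dist_wall <= cfg.septum_thickness + cfg.static_tissue_thickness)
    )
    shape3 = grid.shape
    masks = LumenMasks(
        whole=whole.reshape(shape3),
        tl=tl.reshape(shape3),
        fl=fl.reshape(shape3),
        static_tissue=static.reshape(shape3),
    )

    T = cfg.n_timepoints
    phase = np.arange(T) / T
    w_tl = tl_waveform(phase, cfg.peak_tl_velocity)
    w_fl = fl_waveform(phase, cfg.peak_fl_velocity, cfg.fl_retrograde_fraction)

    prof_tl = np.where(tl, 1.0 - (geo["dist_tl"] / cfg.tl_radius) ** 2, 0.0)
    prof_fl = np.where(fl, 1.0 - (geo["dist_fl"] / cfg.fl_radius) ** 2, 0.0)
    tangent = geo["tangent"]

    # entry-tear jet: cross-septum velocity in a ball around the tear center
    s_tear = cfg.tear_fraction * cfg.length
    tear_center = _tear_center(cfg, s_tear)
    d_tear = np.linalg.norm(pts - tear_center, axis=1)
    jet_prof = np.where(
        (d_tear <= cfg.tear_radius) & whole,
        1.0 - (d_tear / cfg.tear_radius) ** 2,
        0.0,
    )
    jet_dir = geo["septum_normal"]

    n_vox = pts.shape[0]
    v = np.zeros((n_vox, 3, T))
    axial = prof_tl[:, None] * w_tl[None, :] + prof_fl[:, None] * w_fl[None, :]
    # jet pulses with the TL waveform (driven by TL pressurization)
    jet = jet_prof[:, None] * (cfg.tear_jet_velocity / cfg.peak_tl_velocity) * w_tl[None, :]
    for a in range(3):
        v[:, a, :] = tangent[:, a:a + 1] * axial + jet_dir[:, a:a + 1] * jet

    def as_field(varr: np.ndarray) -> VelocityField4D:
        return VelocityField4D(
            vx=np.ascontiguousarray(varr[:, 0, :].reshape(shape3 + (T,))),
            vy=np.ascontiguousarray(varr[:, 1, :].reshape(shape3 + (T,))),
            vz=np.ascontiguousarray(varr[:, 2, :].reshape(shape3 + (T,))),
            grid=grid,
            venc=cfg.venc,
            temporal_resolution=cfg.temporal_resolution_ms,
            rr_interval=cfg.rr_interval_ms,
            gating_mode="retrospective",
        )

    true_field = as_field(v)

    # analytic lumen flow waveforms, mL/s: mean parabolic velocity is half the
    # centerline value; cm/s * mm^2 = 10 mm^3/s = 1e-2 mL/s
    q_tl = 0.5 * w_tl * np.pi * cfg.tl_radius**2 * 1e-2
    q_fl = 0.5 * w_fl * np.pi * cfg.fl_radius**2 * 1e-2

    ss = np.random.SeedSequence(cfg.seed)
    noise_rng = np.random.default_rng(ss.spawn(1)[0])

    field = true_field.copy()
    if cfg.noise_snr is not None:
        field = inject_noise(field, cfg.noise_snr, cfg.peak_tl_velocity, noise_rng)
    if cfg.eddy_coefficients is not None:
        field = inject_eddy_offset(field, cfg.eddy_coefficients)
    wrap_count = 0
    if cfg.aliasing_enabled:
        field, wrap_count = inject_aliasing(field)

    mag3 = np.where(whole, 100.0, np.where(static, 60.0, 1.0)).reshape(shape3)
    magnitude = MagnitudeSeries(
        magnitude=np.repeat(mag3[..., None], T, axis=3), grid=grid
    )

    truth = PhantomGroundTruth(
        true_field=true_field,
        true_masks=dataclasses.replace(masks),
        tl_flow_waveform=q_tl,
        fl_flow_waveform=q_fl,
        wrap_count=wrap_count,
        eddy_coefficients=cfg.eddy_coefficients,
    )
    return field, magnitude, masks, truth


def _tear_center(cfg: PhantomConfig, s: float) -> np.ndarray:
    if cfg.geometry == "straight":
        return np.array([0.0, 0.0, s])
    rc = cfg.arc_radius
    theta = s / rc
    return np.array([rc * (1.0 - np.cos(theta)), 0.0, rc * np.sin(theta)])
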