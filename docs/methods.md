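# Methods

This note documents the models behind `dissectflow`, the parameters that
matter, the numerical choices, and what the synthetic phantom does and does
not establish about real data.

## Quantities and definitions

All internal computation is in SI; velocities enter in cm/s (the native
phase-contrast unit), spatial metadata in mm, timing in ms. Reported units
are J (kinetic energy), m/s (maximum velocity), mL/cycle (forward/reverse
flow), and J / W (viscous energy loss).

**Kinetic energy.** Per voxel and timepoint, `0.5 ρ dV |v(t)|²` with blood
density ρ = 1060 kg/m³ and voxel volume dV. The per-voxel value is the sum
over the retained cycle; the luminal value is the sum over voxels. No time
normalization is applied, so the scalar depends on the retained frame count —
which is why every scan is truncated to the same cycle fraction first
(a `cycle_cutoff_fraction` of 1.0 disables truncation when a cohort is
uniformly retrospectively gated).

**Forward/reverse flow.** The through-plane velocity is `s(t) = v(t)·n̂`,
where `n̂` is the tangent of the nearest centerline plane (see Geometry).
Per voxel, `FF = Σ_t max(s, 0) A Δt` and `RF = Σ_t max(−s, 0) A Δt` with
`A = spacing²` on the isotropic grid and Δt the frame duration — a rectangle
rule in time, matching discrete-frame acquisition. Luminal values are means
over voxels, so they are per-voxel cycle volumes, not lumen totals.

**Maximum velocity.** For each timepoint the 95th percentile (linear
interpolation between order statistics) of voxel speeds inside the lumen is
computed; the timepoint with the highest value is selected (earliest on
ties, independently per lumen) and MV is the mean of speeds at or above that
percentile there. Lumina under 20 voxels make a top-5% ill-defined; the
code warns and uses the plain maximum.

**Viscous energy loss.** The Newtonian dissipation function

    ϕ_v = ½ Σ_ij [ ∂v_j/∂x_i + ∂v_i/∂x_j − ⅔ (∇·v) δ_ij ]²

is evaluated per voxel and timepoint (units s⁻²), then multiplied by the
dynamic viscosity (3.2 cP) and dV to give a dissipation rate in watts.
Cycle-integrated it gives EL_total (J); time-averaged, EL_mean (W); regional
summaries are means over the FL and over the combined descending aorta
(FL plus TL distal to the subclavian-level landmark). The divergence term is
retained even though blood is modeled incompressible: on analytic
divergence-free fields it vanishes to discretization error, and keeping it
makes the implemented formula exactly the printed one.

Spatial gradients use second-order central differences restricted to
in-lumen neighbors, falling back to first-order one-sided stencils at the
wall; voxels outside the lumen never contribute. This avoids the large
artificial shear that differencing against the zeroed background would
create, at the cost of underestimating the true wall shear (the velocity
profile between the last luminal voxel and the wall is not resolved). On the
steady Poiseuille cylinder (R = 8 mm, L = 60 mm, Q = 80 mL/s) the
lumen-summed dissipation is 7.7% below `8μLQ²/(πR⁴)` at 1 mm spacing and
2.4% below at 0.5 mm. Because all stencils stay inside the lumen, adding a
uniform velocity changes nothing (exact Galilean invariance), and rigid
rotation dissipates exactly zero.

## Preprocessing chain

Order: eddy-current correction → noise masking → anti-aliasing → PC-MRA →
cycle truncation → isotropic interpolation. Each step is idempotent under
re-application with the same parameters.

* **Eddy currents.** Residual background phase is modeled as a spatial
  polynomial of order 0 or 1 per velocity component, constant in time — the
  standard stationary-tissue model. It is fit by least squares to the
  time-averaged velocity of static-tissue voxels (≥ 10 required; a
  rank-deficient spatial distribution falls back to order 0 with a warning)
  and subtracted everywhere. On noise-free linear offsets the fit is exact
  to machine precision; under noise the residual static background is the
  time-averaged noise floor, so the correction's benefit is quantified on
  the time-averaged static speed.
* **Noise masking.** Voxels whose time-averaged magnitude falls strictly
  below `noise_threshold` (default 0.1) times the peak time-averaged
  magnitude have their velocities zeroed. The threshold is a free parameter;
  0.1 cleanly separates airspace from tissue in the phantom's three-level
  magnitude model and is typical for phase-contrast masking.
* **Anti-aliasing.** Phase wrapping is detected per voxel by temporal
  continuity: a frame-to-frame jump exceeding venc is attributed to wrapping
  and corrected by the nearest multiple of 2·venc, scanning frames in order
  against the already-corrected predecessor. This is exactly invertible in
  the single-wrap regime provided the first frame is unaliased and true
  frame-to-frame changes stay below venc — both hold for aortic flow at
  typical temporal resolution (velocity ramps to systole over several
  frames). It performs no spatial unwrapping; fields aliased already at the
  first frame, or multi-wrapped, are out of scope.
* **PC-MRA** is the per-voxel time-mean of `vx² + vy² + vz²`, stored without
  square root (a display option applies one). It is invariant to velocity
  sign flips.
* **Cycle truncation.** Cohorts mixing prospectively triggered scans (which
  omit late diastole) with retrospectively gated ones are made comparable by
  retaining the first `floor(T_full × cutoff)` frames of every scan, where
  `T_full = RR / Δt` is the full-cycle frame count and the default cutoff is
  0.673 — the minimum cycle coverage of a prospective scan in the cohort the
  pipeline was designed around. Truncation counts from the first frame
  (prospective triggering acquires from early systole); at least 2 frames
  are always retained. Truncation precedes interpolation for cost.
* **Interpolation.** Each component and timepoint is resampled to an
  isotropic grid (default 1 mm) by cubic B-spline interpolation
  (`map_coordinates`, mirror boundary); masks use nearest neighbor; time is
  never interpolated. Splines reproduce values at shared grid points and
  linear fields exactly in the volume interior; the mirror boundary bends a
  linear extrapolant near the volume faces, with geometrically decaying
  influence inward — irrelevant in practice since the aorta never touches
  the field-of-view edge.

## Geometry

The FL mask is the whole-aorta mask minus the TL mask (an error if the TL
leaves the aorta). The centerline follows the path of TL flow: 3D
skeletonization of the TL, the longest geodesic path through the skeleton
(endpoints are the skeleton voxel pair with maximal geodesic separation,
which suppresses side branches), a 5 mm moving average, a cross-sectional
recentering pass (each point snapped to the centroid of the luminal voxels
in a thin orthogonal slab, correcting the lateral bias of discrete
skeletons), extension of both ends to the mask boundary along the locally
estimated arc (chords over the last ~12 mm give direction and turn rate),
and a smoothing-spline fit resampled at 1 mm arc length. Tangents are the
spline derivative, normalized, and define one orthogonal analysis plane per
point.

Parallel thinning can erode an even-diameter, symmetric tube to nothing
(symmetric voxel pairs are deleted simultaneously); when the skeleton
degenerates the code falls back to the plateau of the Euclidean distance
transform restricted to deep voxels — the same medial locus by another
estimator. Verified accuracy: a straight 8 mm-radius cylinder yields a
centerline within half a voxel of the axis with tangents within 2° of the
axis direction; a quarter torus (60 mm arc radius) yields tangents within 5°
of analytic and arc length within 5%; consecutive plane spacing stays in
[0.9, 1.1] mm.

Each TL and FL voxel is matched to the plane whose *center point* is nearest
(Euclidean); ties break to the more proximal plane for determinism. Distance
to the plane center rather than point-to-plane distance keeps matching
well-defined in curved segments where a voxel lies between several infinite
planes. The matched plane's tangent is the voxel's forward direction.

Anatomic landmarks cannot be detected in a phantom without anatomy, so the
region splits take them as inputs: two arc-length fractions mark the
subclavian-level start of the descending TL and the pulmonary-vein-level
proximal/distal TL boundary; the FL is bisected at the midpoint of its own
assigned arc-length range; the combined descending aorta is the FL plus the
TL distal to the first landmark.

## The phantom

The phantom is an analytic prescription, not a fluid simulation: its purpose
is exact ground truth for every processing stage, under the acquisition
conditions the pipeline targets (venc 160 cm/s, ~2–2.5 mm acquisition
spacing resampled to 1 mm, 8–20 cardiac frames).

Geometry: a straight segment or circular arc carries two parallel circular
tubes — TL (default radius 8 mm) and FL (default 12 mm, the FL is typically
the larger lumen in chronic dissection) — separated by a 1 mm septum, inside
a static-tissue sleeve and airspace with magnitude levels 100/60/1. Flow:
each lumen carries an axial parabolic profile scaled by an analytic
waveform. The TL waveform is a dominant systolic raised cosine (default peak
120 cm/s) plus a small late-diastolic lobe. The FL waveform is a delayed,
slower forward lobe (default peak 40 cm/s) plus a negative lobe beginning in
late systole and extending into diastole — FL flow lags the TL and reverses
as the pressurized lumen empties through tears. The negative lobe's
amplitude is solved so the discretely sampled retrograde volume fraction
equals the configured value exactly (the two lobes are disjoint in time, and
a spatial profile common to both lobes cancels in the ratio). An entry-tear
jet adds a cross-septum velocity bump pulsing with the TL waveform; it is
orthogonal to the centerline tangent and so contributes no through-plane
flow.

Corruptions are applied in image space, in the order noise → eddy offset →
wrapping (measurement noise, then reconstruction background phase, then
readout wrapping): i.i.d. Gaussian velocity noise with σ = peak velocity /
SNR; a per-component offset `a + b·x + c·y + d·z` (world mm) constant in
time; single-wrap aliasing `v → v − 2·venc·sign(v)` wherever |v| > venc
(multi-wrap is out of scope and rejected). The acquisition-side literature
specifies none of these models quantitatively; they are deliberate,
documented stand-ins chosen to be exactly invertible so round trips can be
asserted bit-exactly. All randomness descends from one integer seed through
spawned `SeedSequence` children, so identical configs reproduce identical
scans.

What the phantom does **not** emulate: secondary/helical flow and
turbulence, flap motion (masks are static, matching time-averaged
segmentation practice), partial-volume and intravoxel dephasing at walls,
spatially correlated noise, and anatomic branching. Tests passing on the
phantom therefore validate the *computational* chain — units, geometry,
integration rules, inversion of the corruption models, statistical recovery
— not the physiological fidelity of any particular clinical measurement.

## Synthetic cohorts

The longitudinal generator emulates a 32-patient two-subgroup cohort
(19 : 13 split) with paired scans ≥ 120 days apart (interval lognormal,
median 215 days, clipped to [135, 1689]), baseline descending-aorta
diameters N(45.3, 6.3) mm, and baseline values of the six parameters drawn
from lognormals matched to chronic-dissection magnitudes (TL KE ~0.25 J,
TL MV ~1.4 m/s, TL FF ~0.11 mL/cycle, FL KE ~0.028 J, FL MV ~0.43 m/s,
FL RF ~0.015 mL/cycle).

Growth rate (normal, median 1.1 mm/year, IQR 2.7) and the change in FL RF
are coupled through a Gaussian copula with Pearson parameter
`r = 2 sin(π ρ_s / 6)`, which produces the requested Spearman rank
correlation ρ_s exactly in the population (comonotone at ρ_s = 1). Parameter
changes are generated on the log-ratio scale, `followup = baseline · exp(q)`,
so follow-up values stay positive and the percent change recovered from the
table is a strictly monotone transform of q — rank correlations survive the
round trip undistorted. The other five parameters' changes are independent
of growth. Follow-up diameter is `d₀ + growth · years`, making the tabulated
growth rate exactly recoverable.

Recovery under the study conditions: at n = 2000 the sample rho lands within
±0.05 of a generating 0.45; across 200 cohorts of n = 32 the mean recovered
rho is within ±0.05 of 0.45 with a positive sign in ≥ 95% of seeds; with
ρ_s = 0 the correlation test's type-I error at α = 0.05 is 0.05 ± 0.02 over
1000 seeds.

## Cohort statistics

Growth rate is the absolute diameter change divided by the scan interval
(mm/year; year = 365.25 days) — the definition whose units match the
3 mm/year rapid-growth threshold, which is strict (3.0 exactly is not
rapid). A relative rate (%/year of baseline) is also emitted. Interval
changes are reported both as raw percent and percent per year; the two
orderings differ across patients because intervals vary, so correlation
analyses state which normalization they use (the per-year form is the
default for observational tables; the recovery tests use the raw form, which
is the quantity the copula couples).

Spearman correlations use average ranks; the p-value is the t-distribution
approximation `t = ρ√((n−2)/(1−ρ²))` for n > 10 and an exact permutation
enumeration for n ≤ 10 (all n! orderings, chunked; with ties the statistic
is Pearson-on-ranks). Constant inputs return an explicitly undefined result.
Group comparisons gate on Shapiro–Wilk at α = 0.05 in both groups (t-test if
both normal, Mann–Whitney U otherwise; constant groups skip the normality
test and go nonparametric); one-sided alternatives are supported for
directional hypotheses; categorical tables use chi-square without continuity
correction. No multiple-testing adjustment is applied by default — single
unadjusted p-values at α = 0.05 mirror observational reporting practice — but
a Benjamini–Hochberg helper is available.

## Problem sizes

The test suite and acceptance script run phantoms of 6–10 mm lumen radii,
30–48 mm segment length, 1–2.5 mm grids and 8–16 frames, and cohorts up to
n = 2000 (single draw) or 1000 × n = 32 (operating-characteristic sweeps).
These sizes were chosen so every published invariant is exercised at
discretization levels where its tolerance is meaningful; the algorithms are
resolution-independent and accept full-size scans unchanged.

## Known limitations

* The anti-aliasing detector is temporal only and assumes an unaliased first
  frame and single wraps.
* Wall shear is under-resolved by one-sided stencils; EL values carry a
  resolution-dependent negative bias (quantified above on Poiseuille flow).
* Masks are time-averaged; flap motion is not modeled.
* KE sums depend on the retained frame count; compare scans only after
  truncation to a common cycle window.
* Landmarks for regional splits are operator inputs, not detected.
* The corruption models are stand-ins; acquisition physics (k-space, coils,
  Maxwell terms) is out of scope.
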