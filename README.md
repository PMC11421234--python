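# dissectflow

Voxel-wise 4D-flow MRI hemodynamics of aortic dissection, with the
longitudinal statistics that relate hemodynamic change to aortic growth.

## The problem

In type B aortic dissection the aorta is split by an intimal flap into a true
lumen (TL) and a false lumen (FL). Whether — and how fast — the dissected
descending aorta will dilate is the central question of surveillance, and
diameter alone predicts it poorly. Time-resolved three-directional
phase-contrast MRI (4D flow CMR) measures a velocity vector in every voxel of
the aorta over the cardiac cycle, and voxel-wise summaries of TL and FL flow
— and especially their *changes between serial scans* — carry prognostic
signal about growth.

`dissectflow` implements that analysis chain for people who work with 4D-flow
velocity fields: phase-contrast preprocessing, TL-centerline flow geometry,
the voxel-wise parameter maps, and the paired-scan cohort statistics. Because
clinical dissection datasets are rarely shareable, the package also contains
a synthetic dissected-aorta phantom and a synthetic longitudinal cohort
generator with known ground truth, so every stage is testable end to end.

## What it computes

For each scan, on the preprocessed isotropic velocity field `v(x, t)` (masks
for the whole aorta and the TL are inputs; FL = whole − TL):

* **Kinetic energy** per voxel, summed over the retained cycle and the lumen:
  `KE = Σ_t 0.5 ρ dV |v(t)|²` with ρ = 1060 kg/m³ (joules).
* **Forward / reverse flow**: orthogonal analysis planes are placed every
  millimeter along the TL centerline; each luminal voxel is matched to its
  nearest plane and its velocity projected on the plane normal `n̂`. Positive
  and negative projections integrate separately into per-voxel FF and RF
  (mL/cycle), reported as luminal means.
* **Maximum velocity**: at the timepoint with the highest 95th-percentile
  voxel speed (chosen per lumen), the mean of the top 5% of speeds (m/s).
* **Viscous energy loss** from the Newtonian dissipation function
  `ϕ_v = ½ Σ_ij [∂v_j/∂x_i + ∂v_i/∂x_j − ⅔ (∇·v) δ_ij]²`, multiplied by
  viscosity (3.2 cP) and voxel volume: a dissipation rate per voxel (W),
  cycle-integrated (EL_total, J) and time-averaged (EL_mean, W), summarized
  over the FL and the combined descending aorta.

For each patient with paired scans: aortic growth rate
`(d₁ − d₀) / interval` in mm/year (rapid growth is strictly > 3 mm/year,
intervals under 120 days are excluded), interval changes of every parameter
(% and %/year), Spearman correlations of those changes with growth rate, and
normality-gated two-group comparisons (Shapiro–Wilk deciding t-test vs
Mann–Whitney U; chi-square for categorical tables).

Preprocessing covers the standard phase-contrast chain: static-tissue
eddy-current (background phase) correction, noise masking from the
time-averaged magnitude, temporal-continuity velocity anti-aliasing, PC-MRA
computation (time-mean squared speed), truncation of every scan to a common
67.3% cycle window, and cubic-spline resampling to 1 mm³.

## A worked example

```bash
python examples/01_phantom_and_maps.py
```

builds a two-lumen phantom (TL radius 6 mm, FL radius 8 mm, 30% FL
retrograde volume fraction, SNR 25 velocity noise), runs the full chain and
prints:

```
True lumen  KE  2.64e-03 J   (cycle-summed kinetic energy)
True lumen  MV  1.166 m/s (mean of top-5% voxel speeds)
True lumen  FF  0.0884 mL/cycle (mean forward flow per voxel)
False lumen KE  7.47e-04 J
False lumen MV  0.423 m/s
False lumen RF  0.01180 mL/cycle (mean reverse flow per voxel)

FL retrograde share RF/(FF+RF): 0.313 (generator used 0.30; ...)
```

The TL carries fast systolic flow (MV ≈ 1.2 m/s) while the FL is slower
(MV ≈ 0.4 m/s) with substantial reverse flow — the hemodynamic signature of
a patent false lumen. The recovered retrograde share sits at the generating
0.30. The other examples demonstrate the corruption round trips
(`02_corruption_round_trips.py`), the dissipation estimate against the
Hagen–Poiseuille identity (`03_energy_loss_poiseuille.py`), and the
longitudinal cohort statistics (`04_longitudinal_cohort.py`).

A thin CLI wraps the same library calls for shell use:

```bash
dissectflow phantom --out scan_dir
dissectflow preprocess --in scan_dir --out prep_dir
dissectflow summarize --in prep_dir --out summary.csv
dissectflow cohort simulate --out cohort.csv
dissectflow cohort analyze --cohort-csv cohort.csv --out results.csv
```

## Layout

```
src/dissectflow/
  core.py          velocity-field / grid / mask containers, blood constants
  phantom.py       synthetic dissected-aorta scans + corruption models
  simulate.py      synthetic longitudinal cohorts (Gaussian copula)
  preprocess.py    eddy correction, noise mask, anti-aliasing, PC-MRA,
                   cycle truncation, isotropic interpolation
  geometry.py      FL derivation, TL centerline, orthogonal planes, regions
  hemodynamics.py  KE, FF/RF, MV, viscous energy loss, luminal summaries
  cohort.py        growth rates, interval changes, correlation and group tests
  pipeline.py      per-scan driver and paired-cohort simulation
  io.py            NIfTI + JSON scan layout, centerline CSV
  cli.py           thin command-line interface
```

See `docs/methods.md` for the models, assumptions and numerical choices.
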