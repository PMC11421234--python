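"""Generate a dissected-aorta phantom and quantify its hemodynamics.

Builds a small straight two-lumen phantom with a 30% false-lumen retrograde
fraction, runs the preprocessing chain and centerline geometry, and prints
the six luminal scalars.
"""

from dissectflow import PhantomConfig, generate_phantom
from dissectflow.pipeline import analyze_scan

cfg = PhantomConfig(
    tl_radius=6.0, fl_radius=8.0, length=48.0, grid_spacing=2.0,
    n_timepoints=16, fl_retrograde_fraction=0.3, noise_snr=25.0, seed=7,
)
field, magnitude, masks, truth = generate_phantom(cfg)
summary = analyze_scan(field, magnitude, masks)

print("True lumen  KE  {:.2e} J   (cycle-summed kinetic energy)".format(summary.tl_ke))
print("True lumen  MV  {:.3f} m/s (mean of top-5% voxel speeds)".format(summary.tl_mv))
print("True lumen  FF  {:.4f} mL/cycle (mean forward flow per voxel)".format(summary.tl_ff))
print("False lumen KE  {:.2e} J".format(summary.fl_ke))
print("False lumen MV  {:.3f} m/s".format(summary.fl_mv))
print("False lumen RF  {:.5f} mL/cycle (mean reverse flow per voxel)".format(summary.fl_rf))
print()
print("FL retrograde share RF/(FF+RF): {:.3f} (generator used 0.30; the".format(
    summary.fl_rf / (summary.fl_ff + summary.fl_rf)))
print("67.3% cycle cutoff reweights the systolic and diastolic lobes and the")
print("velocity noise adds unsigned flow, so the preprocessed share deviates")
print("slightly from the full-cycle generating value.")
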