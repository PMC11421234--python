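"""Synthetic longitudinal cohort and the growth-rate correlation analysis.

Generates a 32-patient cohort whose change in false-lumen reverse flow is
rank-correlated (rho = 0.45) with aortic growth rate through a Gaussian
copula, then runs the Spearman analysis over all six parameters.
"""

from dissectflow.cohort import correlate_with_growth
from dissectflow.simulate import PARAMETERS, SyntheticCohortConfig, generate_cohort

cfg = SyntheticCohortConfig(n_patients=32, rho_gen=0.45, seed=11)
df = generate_cohort(cfg)
n_rapid = int(df["rapid"].sum())
print(f"{len(df)} patients ({(df['subgroup'] == 'rTAAD').sum()} rTAAD, "
      f"{(df['subgroup'] == 'dnTBAD').sum()} dnTBAD), "
      f"{n_rapid} with rapid growth (> 3 mm/year)")
print(f"median growth rate {df['growth_rate'].median():.2f} mm/year, "
      f"median interval {df['interval_days'].median():.0f} days")
print()
print("Spearman correlation of interval change (%) with growth rate:")
for p in PARAMETERS:
    res = correlate_with_growth(df, p, normalization="percent")
    flag = " *" if res.p_value < 0.05 else ""
    print(f"  {p:6s} rho = {res.rho:+.2f}  p = {res.p_value:.3f}{flag}")
print()
print("Only the FL RF change is coupled to growth by construction; at n = 32")
print("its correlation should be near the generating 0.45 while the other")
print("parameters fluctuate around zero.")
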