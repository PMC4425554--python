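"""Two-way deterministic sensitivity surfaces.

Sweeps the bed-day price against (a) the infection-DRG share and (b) the
fractional LOS reduction, printing the corners of each net-benefit surface
and where the EUR 0 break-even contour sits.
"""

import stewardcost as sc
from stewardcost import defaults

params = sc.ModelParameters(
    p_drg=70 / 114, p_iv=52 / 70, delta_los=1.37, delta_nursing=73.47,
    delta_ab_cost=0.0, c_bed=716.0, c_nurse_hour=30.0,
    c_audit=sc.audit_cost_total(defaults.DEFAULT_AUDIT_COSTS), n_audit=1.09)

grid = sc.sensitivity_surface(
    params,
    sc.AxisSpec("c_bed", 200.0, 1400.0, 25),
    sc.AxisSpec("p_drg", 0.0, 1.0, 21))
frame = grid.to_dataframe()
print("net benefit (EUR/patient) over bed-day price x infection-DRG share:")
print(f"  corners: {frame.iloc[0, 0]:8.2f}  {frame.iloc[0, -1]:8.2f}")
print(f"           {frame.iloc[-1, 0]:8.2f}  {frame.iloc[-1, -1]:8.2f}")
neg = (grid.values < 0).mean()
print(f"  fraction of grid below break-even: {neg:.1%}")

grid2 = sc.sensitivity_surface(
    params,
    sc.AxisSpec("c_bed", 200.0, 1400.0, 25),
    sc.AxisSpec("los_reduction_fraction", 0.0, 0.5, 21),
    control_los=7.57)
print()
print("surface over bed-day price x % LOS reduction (of a 7.57-day stay):")
print(f"  value at 716 EUR/day, 18% reduction: "
      f"EUR {grid2.values[10, 7]:.2f} per patient")
print(f"  break-even audit price at baseline: "
      f"EUR {sc.break_even_audit_cost(params):.2f}")
print()
print("Cells below EUR 0 are parameter combinations where audits would cost")
print("more than they free up - e.g. cheap wards with few infection-DRG")
print("admissions.")
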