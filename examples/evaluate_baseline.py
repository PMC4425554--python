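"""Evaluate the net-benefit model at the built-in reference calibration.

Builds the point-estimate parameters of the reference urology-ward
evaluation (61.4% infection-DRG share, 1.37-day LOS reduction at EUR 716 a
bed-day, 73.47 min less IV nursing at EUR 30/h for 74.3% IV patients,
antibiotic-cost effect gated out, EUR 80.26 per audit, 1.09 audits/patient)
and prints what one year of day-2 case-audits was worth.
"""

import stewardcost as sc
from stewardcost import defaults

ref = defaults.REFERENCE_DRG1
params = sc.ModelParameters(
    p_drg=70 / 114,
    p_iv=ref.iv_intervention / ref.n_intervention,
    delta_los=ref.los_control - ref.los_intervention,
    delta_nursing=ref.nursing_control - ref.nursing_intervention,
    delta_ab_cost=0.0,
    c_bed=defaults.DEFAULT_COSTS.c_bed,
    c_nurse_hour=defaults.DEFAULT_COSTS.rate_nurse,
    c_audit=sc.audit_cost_total(defaults.DEFAULT_AUDIT_COSTS),
    n_audit=defaults.N_AUDIT_OVERALL,
    n_patients=114,
)

per_patient = sc.per_patient_net_benefit(params)
total = sc.cohort_net_benefit(params)
audit_total = params.c_audit * params.n_audit * params.n_patients

print(f"net benefit per audited patient : EUR {per_patient:9.2f}")
print(f"cohort net benefit (114 pts)    : EUR {total:9.2f}")
print(f"total audit cost                : EUR {audit_total:9.2f}")
print(f"ROI vs audit cost               : {sc.roi(total, audit_total):9.2f}")
print(f"break-even audit price          : EUR "
      f"{sc.break_even_audit_cost(params):9.2f}")
print()
print("A positive net benefit means the freed bed-days, nursing time and")
print("drug savings outweigh the staff time the audits consume; the")
print("break-even price is how expensive one audit could get before the")
print("programme stops paying for itself.")
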