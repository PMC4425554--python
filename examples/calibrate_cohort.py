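"""Calibrate model parameters from a (synthetic) two-arm cohort.

Generates the fixed reference-like cohort (114 audited patients, 357
frequency-matched historic controls), compares each outcome between arms
per DRG group, and shows which effects survive the p < 0.025 gate.
"""

import stewardcost as sc
from stewardcost import defaults

records, truth = sc.table1_fixture()
intervention = [r for r in records if r.arm == "intervention"]
control = [r for r in records if r.arm == "control"]

result = sc.extract_parameters(intervention, control,
                               defaults.DEFAULT_COSTS,
                               defaults.DEFAULT_AUDIT_COSTS)

for group in (1, 2):
    label = "infection DRG" if group == 1 else "underlying disease DRG"
    print(f"DRG group {group} ({label}):")
    for outcome, eff in result.effects[group].items():
        gate = "INCLUDED " if eff.included else "gated out"
        print(f"  {outcome:12s} delta = {eff.delta:8.2f}   "
              f"p = {eff.p_value:6.4f} ({eff.test_name:12s}) -> {gate}")
    params = result.parameters[group]
    print(f"  -> p_drg = {params.p_drg:.4f}, p_iv = {params.p_iv:.4f}, "
          f"n_audit = {params.n_audit:.4f}")
    print(f"  -> per-patient net benefit of this group's effects: "
          f"EUR {sc.per_patient_net_benefit(params):.2f}")
    print()

print(f"combined per-patient net benefit: "
      f"EUR {result.combined_per_patient_net_benefit():.2f}")
print()
print("Only effects with p < 0.025 enter the model (two subgroup analyses")
print("-> halved threshold); a delta of 0 above means the measured change")
print("was not distinguishable from the historic controls.")
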