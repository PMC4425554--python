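"""Built-in default parameter set: the reference urology-ward evaluation.

The package ships the calibrated values of a one-year day-2 case-audit
programme on an academic urology ward (114 audited patients, frequency-matched
historic controls, prices at 2013 Euro level) as its default configuration.
Every value is overridable through :class:`~stewardcost.config.RunConfig`.

Two deliberately redundant figures are stored side by side:

* ``NURSING_MINUTES_PER_DAY`` is the surveyed headline figure for the daily
  nursing burden of IV administration (64.83 min/day).  The itemised task
  times in ``NURSING_COMPONENTS`` do *not* reconstruct it (they total
  ≈38.8 min/day); the survey headline and the component list came from the
  same ward survey but are independent measurements, so neither is derived
  from the other here.
* ``N_AUDIT_OVERALL`` (1.09) is the cohort-wide mean number of case-audits
  per admission, while the per-group means (1.11 infection-DRG, 1.09
  underlying-disease DRG) live in the reference cohort table.  The per-group
  mean is the calibration default; the overall figure is a config override.
"""

from __future__ import annotations

from .model import AuditCostComponents, CostConfig, NursingTimeComponents

#: Unit costs: bed-day price from the ward's internal costing system (2012
#: budgets, overhead included, procedures excluded) and gross hourly salaries.
DEFAULT_COSTS = CostConfig(
    c_bed=716.0,
    rate_specialist=120.0,
    rate_pharmacist=120.0,
    rate_attending=35.0,
    rate_nurse=30.0,
    rate_investigator=25.0,
)

#: Per-audit cost build-up: A-Team doctor time (12.1 min), attending
#: physician discussion, pharmacist alert/clinical-rule maintenance, quality
#: assurance, and miscellaneous (team meetings).  Totals €80.26, of which
#: €69.07 direct personnel cost.
DEFAULT_AUDIT_COSTS = AuditCostComponents(
    ateam_member=24.03,
    attending=7.01,
    pharmacist=35.95,
    investigator=2.08,
    miscellaneous=11.19,
)

#: Itemised IV-administration nursing tasks from the ward survey.
NURSING_COMPONENTS = NursingTimeComponents(
    prep_per_dose=10.5,
    insertion_once=7.5,
    line_change=10.0,
    change_interval=4.0,
    control_per_day=10.0,
    removal_once=2.5,
    doses_per_day=2.27,
    course_length=4.04,
)

#: Surveyed headline daily nursing burden of IV treatment (minutes/day).
NURSING_MINUTES_PER_DAY = 64.83

#: Cohort-wide mean case-audits per admission (per-group means: see REFERENCE_TABLE).
N_AUDIT_OVERALL = 1.09

#: Two-sided significance threshold; fixed at 0.025 to control the familywise
#: error over the two DRG subgroup analyses.
DEFAULT_ALPHA = 0.025

#: Monte-Carlo draws for the probabilistic sensitivity analysis.
DEFAULT_PSA_DRAWS = 2500

#: One-off programme implementation cost (accepted as an input constant; the
#: package never recomputes it and it is excluded from the per-ward model).
IMPLEMENTATION_COST = 17732.0


class ReferenceGroup:
    """Calibrated summary of one DRG group of the reference cohort.

    Means carry 95% CI halfwidths (``*_hw``); counts are patients.  The
    intervention arm is the audited year, the control arm the frequency-matched
    historic cohort.
    """

    def __init__(self, **kw):
        self.__dict__.update(kw)


#: DRG Group 1 — admissions coded for infections / infection-related
#: indications; the group in which the audit produced significant effects.
REFERENCE_DRG1 = ReferenceGroup(
    n_intervention=70,
    n_control=209,
    los_intervention=6.20, los_intervention_hw=0.61,
    los_control=7.57, los_control_hw=0.64,
    iv_intervention=52, iv_control=168,
    nursing_intervention=178.19, nursing_intervention_hw=40.91,
    nursing_control=251.66, nursing_control_hw=32.94,
    ab_intervention=13.34, ab_intervention_hw=4.54,
    ab_control=17.42, ab_control_hw=3.33,
    age_intervention=55.25, age_intervention_hw=3.71,
    age_control=59.35, age_control_hw=2.25,
    male_intervention=0.51, male_control=0.60,
    readmit_intervention=0.17, readmit_control=0.12,
    n_audit=1.11,
)

#: DRG Group 2 — severe underlying disease (e.g. oncology) with a subsequent
#: clinical infection; no significant audit effects in the reference study.
REFERENCE_DRG2 = ReferenceGroup(
    n_intervention=44,
    n_control=148,
    los_intervention=8.36, los_intervention_hw=1.26,
    los_control=8.10, los_control_hw=0.87,
    iv_intervention=32, iv_control=114,
    nursing_intervention=206.70, nursing_intervention_hw=67.72,
    nursing_control=249.66, nursing_control_hw=40.45,
    ab_intervention=15.76, ab_intervention_hw=8.30,
    ab_control=21.47, ab_control_hw=6.56,
    age_intervention=61.12, age_intervention_hw=4.49,
    age_control=64.57, age_control_hw=2.62,
    male_intervention=0.75, male_control=0.84,
    readmit_intervention=0.11, readmit_control=0.20,
    n_audit=1.09,
)

REFERENCE_TABLE = {1: REFERENCE_DRG1, 2: REFERENCE_DRG2}

#: Synthetic DBC-style code vocabulary used by the cohort generator.  Real
#: Dutch DBC codes are not enumerable here; users supply their own list.
INFECTION_DRG_CODES = frozenset(
    {"DBC-INF-01", "DBC-INF-02", "DBC-INF-03", "DBC-INF-04"}
)
OTHER_DRG_CODES = frozenset({"DBC-ONC-01", "DBC-ONC-02", "DBC-URO-01", "DBC-URO-02"})
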