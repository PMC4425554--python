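"""Calibration: from raw patient records to model parameters.

Turns an intervention cohort (audited patients) and a historic control cohort
into :class:`~stewardcost.model.ModelParameters`, one set per DRG group:

1. assign each admission to DRG Group 1 (infection-related diagnosis codes)
   or Group 2 (severe underlying disease with subsequent infection);
2. optionally filter the historic pool so its diagnosis-code frequencies
   match the intervention cohort's (largest-remainder apportionment, seeded
   sampling without replacement);
3. summarise each group × arm (means with t-based 95% CIs, proportions);
4. test each outcome between arms (Welch t, Mann-Whitney U, chi-square, or
   log-rank on time-to-discharge) and gate the effect: a delta enters the
   model only when its two-sided p-value is below alpha (0.025 by default,
   controlling the familywise error over the two subgroup analyses);
5. assemble per-group ModelParameters, zeroing gated-out deltas.

Missing outcome values (NaN) are excluded listwise per outcome; exclusions
are counted and logged.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .errors import (
    ConfigurationError,
    InsufficientDataError,
    MatchingError,
    ValidationError,
)
from .model import AuditCostComponents, CostConfig, ModelParameters, audit_cost_total

logger = logging.getLogger(__name__)

__all__ = [
    "PatientRecord",
    "GroupSummary",
    "GatedEffect",
    "CalibrationResult",
    "DEFAULT_TEST_MAP",
    "assign_drg_group",
    "assign_groups",
    "frequency_match",
    "summarize_group",
    "compare_outcome",
    "extract_parameters",
]

ARMS = ("intervention", "control")
MEAN_OUTCOMES = ("los", "iv_nursing", "ab_cost", "age")
BINARY_OUTCOMES = ("readmission", "sex", "iv_treated")

#: Default outcome→test mapping (mirrors the reference study's footnotes);
#: override via the ``test_map`` argument of the comparison functions.
DEFAULT_TEST_MAP: Mapping[str, str] = {
    "los": "log_rank",
    "iv_nursing": "welch_t",
    "ab_cost": "mann_whitney",
    "age": "mann_whitney",
    "readmission": "chi_square",
    "sex": "chi_square",
}


@dataclass(frozen=True)
class PatientRecord:
    """One hospital admission.

    ``iv_nursing_minutes`` is the nursing time spent on IV administration over
    the whole stay and must be 0 for patients never on IV treatment.
    ``n_consults`` counts stewardship case-audits (0 for historic controls).
    """

    patient_id: str
    arm: str
    drg_code: str
    drg_group: int
    age: float
    sex: str
    los_days: float
    iv_treated: bool
    iv_nursing_minutes: float
    ab_cost: float
    n_consults: int
    readmitted: bool

    def __post_init__(self) -> None:
        if self.arm not in ARMS:
            raise ValidationError(f"arm must be one of {ARMS}, got {self.arm!r}",
                                  field="arm")
        if self.drg_group not in (1, 2):
            raise ValidationError("drg_group must be 1 or 2", field="drg_group")
        if self.sex not in ("M", "F"):
            raise ValidationError("sex must be 'M' or 'F'", field="sex")
        if not self.los_days > 0:
            raise ValidationError("los_days must be positive", field="los_days")
        if not self.iv_treated and self.iv_nursing_minutes != 0:
            raise ValidationError(
                "iv_nursing_minutes must be 0 for non-IV patients",
                field="iv_nursing_minutes")
        if self.iv_nursing_minutes < 0:
            raise ValidationError("iv_nursing_minutes must be >= 0",
                                  field="iv_nursing_minutes")
        if not math.isnan(self.ab_cost) and self.ab_cost < 0:
            raise ValidationError("ab_cost must be >= 0", field="ab_cost")
        if self.n_consults < 0:
            raise ValidationError("n_consults must be >= 0", field="n_consults")


@dataclass(frozen=True)
class GroupSummary:
    """Mean (or proportion) of one outcome in one group × arm."""

    n: int
    mean: float
    ci95_halfwidth: float
    is_proportion: bool = False
    n_missing: int = 0


@dataclass(frozen=True)
class GatedEffect:
    """A between-arm effect with its significance gate.

    ``delta`` is control mean minus intervention mean (positive = the
    intervention lowered the outcome).  ``included`` is True exactly when
    ``p_value < alpha``; gated-out effects contribute 0 to the model.
    """

    outcome: str
    delta: float
    test_name: str
    p_value: float
    alpha: float
    included: bool

    def __post_init__(self) -> None:
        if self.included != (self.p_value < self.alpha):
            raise ValidationError("included flag inconsistent with p_value/alpha",
                                  field="included")

    @property
    def gated_delta(self) -> float:
        return self.delta if self.included else 0.0


def assign_drg_group(record: PatientRecord, infection_codes: Iterable[str]) -> int:
    """DRG group of a record: 1 if its diagnosis code is infection-related."""
    codes = set(infection_codes)
    if not codes:
        raise ValidationError("infection_codes must be non-empty",
                              field="infection_codes")
    if not record.drg_code:
        raise ValidationError("empty drg_code", field="drg_code")
    return 1 if record.drg_code in codes else 2


def assign_groups(records: Sequence[PatientRecord],
                  infection_codes: Iterable[str]) -> list[PatientRecord]:
    """Records with ``drg_group`` recomputed from their diagnosis codes."""
    codes = set(infection_codes)
    return [replace(r, drg_group=assign_drg_group(r, codes)) for r in records]


def _largest_remainder(weights: Sequence[float], total: int) -> list[int]:
    """Apportion ``total`` integer units proportionally to ``weights``."""
    weight_sum = float(sum(weights))
    quotas = [w / weight_sum * total for w in weights]
    counts = [int(math.floor(q)) for q in quotas]
    remainder = total - sum(counts)
    # distribute leftover units by descending fractional part (ties: first wins)
    order = sorted(range(len(quotas)),
                   key=lambda i: (quotas[i] - counts[i], -i), reverse=True)
    for i in order[:remainder]:
        counts[i] += 1
    return counts


def frequency_match(pool: Sequence[PatientRecord],
                    reference: Sequence[PatientRecord],
                    n_target: int,
                    seed: int | np.random.Generator = 0) -> list[PatientRecord]:
    """Subsample ``pool`` to mirror the diagnosis-code mix of ``reference``.

    Per-code target counts follow largest-remainder apportionment of
    ``n_target`` over the reference code frequencies; patients are then drawn
    without replacement within each code.  Reproducible under ``seed``.
    """
    if not pool or not reference:
        raise MatchingError("pool and reference must be non-empty")
    if n_target < 0 or n_target > len(pool):
        raise MatchingError(
            f"n_target must be in [0, {len(pool)}], got {n_target}")
    ref_counts = Counter(r.drg_code for r in reference)
    pool_by_code: dict[str, list[PatientRecord]] = {}
    for r in pool:
        pool_by_code.setdefault(r.drg_code, []).append(r)
    missing = sorted(set(ref_counts) - set(pool_by_code))
    if missing:
        raise MatchingError(f"reference codes absent from pool: {missing}")

    codes = sorted(ref_counts)
    targets = _largest_remainder([ref_counts[c] for c in codes], n_target)
    shortfall = {c: t - len(pool_by_code[c])
                 for c, t in zip(codes, targets) if t > len(pool_by_code[c])}
    if shortfall:
        raise MatchingError(
            "pool too small for target frequencies; short by "
            + ", ".join(f"{c}: {k}" for c, k in sorted(shortfall.items())))

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    matched: list[PatientRecord] = []
    for code, t in zip(codes, targets):
        members = pool_by_code[code]
        idx = rng.choice(len(members), size=t, replace=False)
        matched.extend(members[i] for i in sorted(idx))
    return matched


def _outcome_values(records: Sequence[PatientRecord], outcome: str) -> np.ndarray:
    if outcome == "los":
        vals = [r.los_days for r in records]
    elif outcome == "iv_nursing":
        vals = [r.iv_nursing_minutes for r in records if r.iv_treated]
    elif outcome == "ab_cost":
        vals = [r.ab_cost for r in records]
    elif outcome == "age":
        vals = [r.age for r in records]
    elif outcome == "readmission":
        vals = [float(r.readmitted) for r in records]
    elif outcome == "sex":
        vals = [float(r.sex == "M") for r in records]
    elif outcome == "iv_treated":
        vals = [float(r.iv_treated) for r in records]
    elif outcome == "n_consults":
        vals = [float(r.n_consults) for r in records]
    else:
        raise ConfigurationError(f"unknown outcome {outcome!r}")
    arr = np.asarray(vals, dtype=float)
    n_missing = int(np.isnan(arr).sum())
    if n_missing:
        logger.warning("%s: excluding %d record(s) with missing values",
                       outcome, n_missing)
    return arr[~np.isnan(arr)]


def summarize_group(records: Sequence[PatientRecord], outcome: str) -> GroupSummary:
    """Mean and t-based 95% CI halfwidth of one outcome (df = n - 1).

    For binary outcomes the mean is a proportion.  ``iv_nursing`` is averaged
    over IV-treated patients only.
    """
    raw_n = len(records) if outcome != "iv_nursing" else sum(
        r.iv_treated for r in records)
    values = _outcome_values(records, outcome)
    is_prop = outcome in BINARY_OUTCOMES
    if is_prop:
        if values.size < 1:
            raise InsufficientDataError(f"{outcome}: no records for a proportion")
    elif values.size < 2:
        raise InsufficientDataError(
            f"{outcome}: need >= 2 non-missing values for a CI, got {values.size}")
    n = int(values.size)
    mean = float(values.mean())
    if n >= 2:
        sd = float(values.std(ddof=1))
        halfwidth = float(stats.t.ppf(0.975, n - 1) * sd / math.sqrt(n))
    else:
        halfwidth = 0.0
    return GroupSummary(n=n, mean=mean, ci95_halfwidth=halfwidth,
                        is_proportion=is_prop, n_missing=raw_n - n)


def _two_sample_p(x: np.ndarray, y: np.ndarray, test_name: str) -> float:
    """Two-sided p-value comparing samples ``x`` (intervention) and ``y``."""
    if test_name == "welch_t":
        return float(stats.ttest_ind(x, y, equal_var=False).pvalue)
    if test_name == "mann_whitney":
        return float(stats.mannwhitneyu(x, y, alternative="two-sided").pvalue)
    if test_name == "chi_square":
        if not (set(np.unique(x)) <= {0.0, 1.0} and set(np.unique(y)) <= {0.0, 1.0}):
            raise ConfigurationError("chi_square requires binary outcomes")
        table = np.array([[x.sum(), len(x) - x.sum()],
                          [y.sum(), len(y) - y.sum()]])
        if (table.sum(axis=0) == 0).any():
            return 1.0
        return float(stats.chi2_contingency(table, correction=False).pvalue)
    if test_name == "log_rank":
        if (x <= 0).any() or (y <= 0).any():
            raise ConfigurationError("log_rank requires positive times")
        from lifelines.statistics import logrank_test

        # discharge is the event; no censoring is modelled
        res = logrank_test(x, y, event_observed_A=np.ones_like(x),
                           event_observed_B=np.ones_like(y))
        return float(res.p_value)
    raise ConfigurationError(f"unknown test {test_name!r}")


def compare_outcome(intervention: Sequence[PatientRecord],
                    control: Sequence[PatientRecord],
                    outcome: str,
                    test_name: str | None = None,
                    alpha: float = 0.025) -> GatedEffect:
    """Between-arm effect on ``outcome`` with its significance gate.

    ``delta`` is control mean minus intervention mean; the two-sided p-value
    comes from ``test_name`` (default per :data:`DEFAULT_TEST_MAP`); the
    effect is flagged ``included`` iff p < alpha.
    """
    if not intervention or not control:
        raise InsufficientDataError("both arms must be non-empty")
    if test_name is None:
        try:
            test_name = DEFAULT_TEST_MAP[outcome]
        except KeyError:
            raise ConfigurationError(f"no default test for outcome {outcome!r}")
    x = _outcome_values(intervention, outcome)
    y = _outcome_values(control, outcome)
    if x.size == 0 or y.size == 0:
        raise InsufficientDataError(f"{outcome}: an arm has no usable values")
    if np.array_equal(np.sort(x), np.sort(y)):
        # identical samples: no evidence of any effect
        delta, p_value = 0.0, 1.0
    else:
        delta = float(y.mean() - x.mean())
        p_value = float(np.clip(_two_sample_p(x, y, test_name), 0.0, 1.0))
    return GatedEffect(outcome=outcome, delta=delta, test_name=test_name,
                       p_value=p_value, alpha=alpha, included=p_value < alpha)


@dataclass
class CalibrationResult:
    """Everything the calibration step produces, per DRG group.

    ``parameters[g]`` evaluates the model for group ``g`` alone: its
    ``p_drg`` is the share of intervention patients in that group, its deltas
    are that group's gated effects, and ``n_patients`` is the full audited
    cohort (groups outside ``g`` contribute no savings by construction).
    """

    parameters: dict[int, ModelParameters]
    effects: dict[int, dict[str, GatedEffect]]
    summaries: dict[int, dict[str, dict[str, GroupSummary]]]
    n_intervention: int
    n_control: int
    alpha: float
    test_map: dict[str, str] = field(default_factory=dict)

    @property
    def n_audit_overall(self) -> float:
        """Cohort-wide mean audits per patient (group means weighted by p_drg)."""
        return sum(p.p_drg * p.n_audit for p in self.parameters.values())

    def combined_per_patient_net_benefit(self, n_audit: float | None = None) -> float:
        """Net benefit per audited patient with both DRG groups' effects.

        Sums each group's share-weighted bracketed savings and subtracts the
        audit cost once, at ``n_audit`` audits per patient (default: the
        cohort-wide mean).  Groups whose effects were all gated out contribute
        nothing to the savings but still share the audit cost.
        """
        if not self.parameters:
            raise InsufficientDataError("no calibrated groups")
        some = next(iter(self.parameters.values()))
        if n_audit is None:
            n_audit = self.n_audit_overall
        savings = sum(
            p.p_drg * (p.delta_los * p.c_bed
                       + p.p_iv * p.delta_nursing * p.c_nurse_hour / 60.0
                       + p.delta_ab_cost)
            for p in self.parameters.values())
        return savings - some.c_audit * n_audit


def extract_parameters(intervention: Sequence[PatientRecord],
                       control: Sequence[PatientRecord],
                       costs: CostConfig,
                       audit: AuditCostComponents,
                       alpha: float = 0.025,
                       test_map: Mapping[str, str] | None = None,
                       ) -> CalibrationResult:
    """Calibrate per-DRG-group model parameters from two cohorts.

    For each group present in the intervention arm: compare LOS, IV nursing
    time and antibiotic cost between arms, gate each delta at ``alpha``, and
    assemble :class:`ModelParameters` with ``p_iv`` and ``n_audit`` taken from
    the group's intervention patients and unit costs from ``costs``/``audit``.
    Readmission, age and sex are compared for reporting only.
    """
    if not intervention or not control:
        raise InsufficientDataError("both cohorts must be non-empty")
    tmap = dict(DEFAULT_TEST_MAP)
    if test_map:
        tmap.update(test_map)
    c_audit = audit_cost_total(audit)

    n_int = len(intervention)
    parameters: dict[int, ModelParameters] = {}
    effects: dict[int, dict[str, GatedEffect]] = {}
    summaries: dict[int, dict[str, dict[str, GroupSummary]]] = {}

    for group in (1, 2):
        gi = [r for r in intervention if r.drg_group == group]
        gc = [r for r in control if r.drg_group == group]
        if not gi or not gc:
            logger.warning("DRG group %d absent from an arm; skipped", group)
            continue
        summaries[group] = {"intervention": {}, "control": {}}
        for arm_name, arm_records in (("intervention", gi), ("control", gc)):
            for outcome in ("los", "iv_nursing", "ab_cost", "age",
                            "iv_treated", "sex", "readmission"):
                try:
                    summaries[group][arm_name][outcome] = summarize_group(
                        arm_records, outcome)
                except InsufficientDataError:
                    pass
        effects[group] = {}
        for outcome in ("los", "iv_nursing", "ab_cost", "age", "readmission"):
            try:
                effects[group][outcome] = compare_outcome(
                    gi, gc, outcome, tmap.get(outcome), alpha)
            except InsufficientDataError:
                logger.warning("group %d, %s: not enough data to compare",
                               group, outcome)
        eff = effects[group]
        n_iv = sum(r.iv_treated for r in gi)
        parameters[group] = ModelParameters(
            p_drg=len(gi) / n_int,
            p_iv=n_iv / len(gi),
            delta_los=eff["los"].gated_delta if "los" in eff else 0.0,
            delta_nursing=eff["iv_nursing"].gated_delta if "iv_nursing" in eff else 0.0,
            delta_ab_cost=eff["ab_cost"].gated_delta if "ab_cost" in eff else 0.0,
            c_bed=costs.c_bed,
            c_nurse_hour=costs.rate_nurse,
            c_audit=c_audit,
            n_audit=float(np.mean([r.n_consults for r in gi])),
            n_patients=n_int,
        )

    return CalibrationResult(parameters=parameters, effects=effects,
                             summaries=summaries, n_intervention=n_int,
                             n_control=len(control), alpha=alpha, test_map=tmap)
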