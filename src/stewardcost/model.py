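"""Cost-minimization model of a day-2 antibiotic case-audit.

The model compares the cost of structured antibiotic reviews ("case-audits"
by a stewardship team, 48 h after therapy start) against the savings they
generate, from a hospital perspective.  Savings arise in the fraction of
patients admitted for an infection-related diagnosis group (``p_drg``) via
three channels: a shorter length of stay, less nursing time spent on IV
administration (through earlier IV→oral switches), and cheaper antibiotic
therapy.  Per audited patient,

    net_benefit = p_drg * ( delta_los * c_bed
                          + p_iv * delta_nursing * c_nurse_hour / 60
                          + delta_ab_cost )
                  - c_audit * n_audit

with ``delta_*`` the control-minus-intervention differences in days, minutes
and Euros.  Deltas may be negative (a harmful intervention yields a negative
net benefit; nothing is clamped).  Nursing time is measured in minutes, so
the hourly nurse wage is divided by 60.

The module also houses the per-audit cost aggregation, the itemised
IV-nursing time model, and consumer-price-index adjustment of historical
prices.  All arithmetic is done at full floating precision; rounding to
whole cents is a reporting concern.
"""

from __future__ import annotations

from dataclasses import dataclass, fields, replace

from .errors import ParameterDomainError

__all__ = [
    "ModelParameters",
    "AuditCostComponents",
    "NursingTimeComponents",
    "CostConfig",
    "per_patient_net_benefit",
    "cohort_net_benefit",
    "break_even_audit_cost",
    "roi",
    "audit_cost_total",
    "audit_personnel_subtotal",
    "nursing_course_minutes",
    "adjust_price_index",
]


def _require(condition: bool, field: str, message: str) -> None:
    if not condition:
        raise ParameterDomainError(field, message)


@dataclass(frozen=True)
class ModelParameters:
    """The calibrated symbols of the net-benefit formula plus cohort size.

    Parameters
    ----------
    p_drg
        Share of patients in the infection-related diagnosis group, in [0, 1].
        Only these patients are assumed to respond to the audit.
    p_iv
        Share of audited patients on IV treatment, in [0, 1].
    delta_los
        Control minus intervention mean length of stay, days.
    delta_nursing
        Control minus intervention mean IV nursing time, minutes per patient.
    delta_ab_cost
        Control minus intervention mean antibiotic cost, EUR per patient
        (0 when the effect is gated out of the point estimate).
    c_bed
        Cost of one patient bed-day, EUR.
    c_nurse_hour
        Gross nurse salary, EUR per hour (applied to minutes via /60).
    c_audit
        Cost of one case-audit, EUR.
    n_audit
        Mean number of case-audits per admitted patient.
    n_patients
        Number of audited patients in the evaluated period.
    """

    p_drg: float
    p_iv: float
    delta_los: float
    delta_nursing: float
    delta_ab_cost: float
    c_bed: float
    c_nurse_hour: float
    c_audit: float
    n_audit: float
    n_patients: int = 0

    def __post_init__(self) -> None:
        _require(0.0 <= self.p_drg <= 1.0, "p_drg", "must lie in [0, 1]")
        _require(0.0 <= self.p_iv <= 1.0, "p_iv", "must lie in [0, 1]")
        for name in ("c_bed", "c_nurse_hour", "c_audit", "n_audit", "n_patients"):
            _require(getattr(self, name) >= 0, name, "must be non-negative")
        for name in ("delta_los", "delta_nursing", "delta_ab_cost"):
            value = float(getattr(self, name))
            _require(value == value and abs(value) != float("inf"), name, "must be finite")

    def with_overrides(self, **overrides: float) -> "ModelParameters":
        """Return a copy with the named fields replaced (re-validated)."""
        valid = {f.name for f in fields(self)}
        unknown = set(overrides) - valid
        if unknown:
            raise ParameterDomainError(sorted(unknown)[0], "unknown model parameter")
        return replace(self, **overrides)


@dataclass(frozen=True)
class AuditCostComponents:
    """Per-audit cost build-up, EUR per audit.

    The first four components are direct personnel costs (stewardship team
    member, attending physician, pharmacist, quality-assurance investigator);
    ``miscellaneous`` covers e.g. team meetings.
    """

    ateam_member: float
    attending: float
    pharmacist: float
    investigator: float
    miscellaneous: float

    def __post_init__(self) -> None:
        for f in fields(self):
            _require(getattr(self, f.name) >= 0, f.name, "must be non-negative")


@dataclass(frozen=True)
class NursingTimeComponents:
    """Itemised nursing tasks for one IV antibiotic course.

    Times in minutes; ``change_interval`` (days between IV line changes),
    ``doses_per_day`` and ``course_length`` (days) shape the course.
    """

    prep_per_dose: float
    insertion_once: float
    line_change: float
    change_interval: float
    control_per_day: float
    removal_once: float
    doses_per_day: float
    course_length: float

    def __post_init__(self) -> None:
        for f in fields(self):
            _require(getattr(self, f.name) >= 0, f.name, "must be non-negative")
        _require(self.change_interval > 0, "change_interval", "must be positive")
        _require(self.course_length > 0, "course_length", "must be positive")


@dataclass(frozen=True)
class CostConfig:
    """Unit costs: bed-day price and gross hourly salaries (EUR).

    ``cpi_source_index``/``cpi_target_index`` allow consumer-price-index
    adjustment of amounts quoted at another price level.
    """

    c_bed: float
    rate_specialist: float
    rate_pharmacist: float
    rate_attending: float
    rate_nurse: float
    rate_investigator: float
    cpi_source_index: float = 100.0
    cpi_target_index: float = 100.0

    def __post_init__(self) -> None:
        for name in ("c_bed", "rate_specialist", "rate_pharmacist",
                     "rate_attending", "rate_nurse", "rate_investigator"):
            _require(getattr(self, name) >= 0, name, "must be non-negative")
        for name in ("cpi_source_index", "cpi_target_index"):
            _require(getattr(self, name) > 0, name, "must be positive")


def per_patient_net_benefit(params: ModelParameters) -> float:
    """Net benefit of auditing one patient, EUR (negative = net cost).

    Evaluates the model formula at ``params``; affine in every delta and in
    the audit cost, so closed-form sensitivity results are exact.
    """
    bracket = (
        params.delta_los * params.c_bed
        + params.p_iv * params.delta_nursing * params.c_nurse_hour / 60.0
        + params.delta_ab_cost
    )
    return params.p_drg * bracket - params.c_audit * params.n_audit


def cohort_net_benefit(params: ModelParameters) -> float:
    """Total net benefit over ``params.n_patients`` audited patients, EUR."""
    return params.n_patients * per_patient_net_benefit(params)


def break_even_audit_cost(params: ModelParameters) -> float:
    """Audit price at which the per-patient net benefit is exactly zero.

    Closed form ``p_drg * bracket / n_audit``; requires ``n_audit > 0``.
    """
    if params.n_audit <= 0:
        raise ParameterDomainError("n_audit", "break-even undefined for n_audit <= 0")
    bracket_value = per_patient_net_benefit(
        params.with_overrides(c_audit=0.0)
    )
    return bracket_value / params.n_audit


def roi(total_benefit: float, total_cost: float) -> float:
    """Return on investment: total benefit divided by total cost."""
    if total_cost <= 0:
        raise ParameterDomainError("total_cost", "must be positive for an ROI")
    return total_benefit / total_cost


def audit_cost_total(components: AuditCostComponents) -> float:
    """Cost of one case-audit: sum of all five components, EUR."""
    return (
        components.ateam_member
        + components.attending
        + components.pharmacist
        + components.investigator
        + components.miscellaneous
    )


def audit_personnel_subtotal(components: AuditCostComponents) -> float:
    """Direct personnel cost of one audit (all components but miscellaneous)."""
    return (
        components.ateam_member
        + components.attending
        + components.pharmacist
        + components.investigator
    )


def nursing_course_minutes(c: NursingTimeComponents) -> tuple[float, float]:
    """Total and per-day nursing minutes for one IV course.

    Preparation scales with doses, line control with days, line changes with
    ``course_length / change_interval`` (fractional changes pro-rated);
    insertion and removal are one-off.
    """
    total = (
        c.prep_per_dose * c.doses_per_day * c.course_length
        + c.insertion_once
        + c.line_change * (c.course_length / c.change_interval)
        + c.control_per_day * c.course_length
        + c.removal_once
    )
    return total, total / c.course_length


def adjust_price_index(amount: float, source_index: float, target_index: float) -> float:
    """Re-express ``amount`` at another price level via a CPI ratio."""
    if source_index <= 0:
        raise ParameterDomainError("source_index", "must be positive")
    if target_index <= 0:
        raise ParameterDomainError("target_index", "must be positive")
    return amount * target_index / source_index
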