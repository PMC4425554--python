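"""Synthetic cohort generator with known ground truth.

Emulates the data structure the calibration step consumes — an intervention
arm of audited patients and a historic control arm, each split over two DRG
groups — with configurable true effects on length of stay, IV nursing time
and antibiotic cost.  Distribution choices follow stylised facts of hospital
data rather than any particular dataset:

* LOS ~ gamma (positive, right-skewed), parameterised by mean and SD;
* IV nursing minutes ~ normal truncated at 0, with the location shifted so
  the *post-truncation* mean equals the configured mean;
* antibiotic cost ~ lognormal, moment-matched to mean and SD;
* consultations per audited patient = 1 + Poisson(mean − 1), so every
  audited patient has at least one case-audit;
* IV treatment, sex and readmission ~ Bernoulli.

``exact_sizes`` pins arm/group/IV-count margins to their expectations
(instead of sampling them), and ``match_means`` rescales each positive
outcome sample so its realised mean equals the configured mean exactly —
together these produce fixtures whose summary table reproduces a target
table, while leaving individual-level variation realistic.

:func:`table1_fixture` applies this to the reference urology cohort, giving
a 114-patient intervention arm and 357-patient control arm whose per-group
summaries land on the reference table's means.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from . import defaults
from .calibration import PatientRecord
from .errors import ConfigurationError

logger = logging.getLogger(__name__)

__all__ = [
    "ArmOutcomeConfig",
    "GeneratorConfig",
    "GroundTruth",
    "generate_cohort",
    "table1_generator_config",
    "table1_fixture",
]


@dataclass(frozen=True)
class ArmOutcomeConfig:
    """Outcome distributions for one DRG group × arm."""

    los_mean: float
    los_sd: float
    iv_prob: float
    nursing_mean: float
    nursing_sd: float
    ab_mean: float
    ab_sd: float
    age_mean: float = 60.0
    age_sd: float = 15.0
    male_prob: float = 0.6
    readmit_prob: float = 0.15
    consult_mean: float = 1.1  # audited arm only; >= 1

    def __post_init__(self) -> None:
        for name in ("los_mean", "los_sd", "nursing_mean", "nursing_sd",
                     "ab_mean", "ab_sd", "age_sd"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        for name in ("iv_prob", "male_prob", "readmit_prob"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1]")
        if self.consult_mean < 1.0:
            raise ConfigurationError("consult_mean must be >= 1")


@dataclass(frozen=True)
class GeneratorConfig:
    """Sizes, group mix and per-group/arm outcome models of a synthetic study."""

    n_intervention: int
    n_control: int
    drg1_fraction: float
    outcomes: dict[int, dict[str, ArmOutcomeConfig]]
    #: control-arm infection-DRG share; defaults to the intervention share
    drg1_fraction_control: float | None = None
    seed: int = 0
    exact_sizes: bool = False
    match_means: bool = False
    group_codes: dict[int, tuple[str, ...]] = field(default_factory=lambda: {
        1: tuple(sorted(defaults.INFECTION_DRG_CODES)),
        2: tuple(sorted(defaults.OTHER_DRG_CODES)),
    })

    def __post_init__(self) -> None:
        if self.n_intervention < 0 or self.n_control < 0:
            raise ConfigurationError("cohort sizes must be >= 0")
        if not 0.0 <= self.drg1_fraction <= 1.0:
            raise ConfigurationError("drg1_fraction must lie in [0, 1]")
        if (self.drg1_fraction_control is not None
                and not 0.0 <= self.drg1_fraction_control <= 1.0):
            raise ConfigurationError("drg1_fraction_control must lie in [0, 1]")
        for group in (1, 2):
            if group not in self.outcomes:
                raise ConfigurationError(f"outcomes for DRG group {group} missing")
            for arm in ("intervention", "control"):
                if arm not in self.outcomes[group]:
                    raise ConfigurationError(
                        f"outcomes for group {group}/{arm} missing")


@dataclass(frozen=True)
class GroundTruth:
    """The generating effects: what calibration should recover."""

    p_drg: float
    delta_los: dict[int, float]
    delta_nursing: dict[int, float]
    delta_ab_cost: dict[int, float]
    p_iv: dict[int, float]
    n_audit: dict[int, float]


def _truncnorm_location(target_mean: float, sd: float) -> float:
    """Location mu such that a N(mu, sd) truncated at 0 has mean target_mean."""

    def post_mean(mu: float) -> float:
        a = -mu / sd
        return float(stats.truncnorm.mean(a, np.inf, loc=mu, scale=sd))

    lo, hi = -10.0 * sd, target_mean + 10.0 * sd
    return float(optimize.brentq(lambda m: post_mean(m) - target_mean, lo, hi,
                                 xtol=1e-9 * max(1.0, target_mean)))


def _sample_truncnorm(rng: np.random.Generator, mean: float, sd: float,
                      size: int) -> np.ndarray:
    mu = _truncnorm_location(mean, sd)
    return stats.truncnorm.rvs(-mu / sd, np.inf, loc=mu, scale=sd,
                               size=size, random_state=rng)


def _sample_lognormal(rng: np.random.Generator, mean: float, sd: float,
                      size: int) -> np.ndarray:
    sigma2 = math.log1p((sd / mean) ** 2)
    mu = math.log(mean) - sigma2 / 2.0
    return rng.lognormal(mu, math.sqrt(sigma2), size)


def _bern(rng: np.random.Generator, p: float, n: int, exact: bool) -> np.ndarray:
    """Bernoulli flags; with ``exact`` the count is fixed at round(p*n)."""
    if not exact:
        return rng.random(n) < p
    flags = np.zeros(n, dtype=bool)
    flags[: round(p * n)] = True
    return rng.permutation(flags)


def _split_group1(rng: np.random.Generator, n: int, frac: float,
                  exact: bool) -> np.ndarray:
    return _bern(rng, frac, n, exact)


def _consult_counts(rng: np.random.Generator, mean: float, n: int,
                    match: bool) -> np.ndarray:
    if n == 0:
        return np.zeros(0, dtype=int)
    if match:
        extras = np.zeros(n, dtype=int)
        extras[: round((mean - 1.0) * n)] = 1
        extras = rng.permutation(extras)
    else:
        extras = rng.poisson(mean - 1.0, n)
    return 1 + extras


def _rescale_to_mean(values: np.ndarray, target: float) -> np.ndarray:
    if values.size == 0 or values.mean() == 0:
        return values
    return values * (target / values.mean())


def _generate_arm(rng: np.random.Generator, arm: str, n: int, config:
                  GeneratorConfig, start_id: int) -> list[PatientRecord]:
    records: list[PatientRecord] = []
    if n == 0:
        logger.warning("generated an empty %s arm (n=0)", arm)
        return records
    frac = config.drg1_fraction
    if arm == "control" and config.drg1_fraction_control is not None:
        frac = config.drg1_fraction_control
    in_group1 = _split_group1(rng, n, frac, config.exact_sizes)
    indices = np.arange(n)
    for group in (1, 2):
        idx = indices[in_group1] if group == 1 else indices[~in_group1]
        m = idx.size
        if m == 0:
            continue
        oc = config.outcomes[group][arm]
        codes = config.group_codes[group]
        # geometric-ish fixed code mix so frequency matching has structure
        code_probs = np.array([2.0 ** -k for k in range(len(codes))])
        code_probs /= code_probs.sum()
        drg_codes = rng.choice(codes, size=m, p=code_probs)
        los = rng.gamma((oc.los_mean / oc.los_sd) ** 2,
                        oc.los_sd ** 2 / oc.los_mean, m)
        iv = _bern(rng, oc.iv_prob, m, config.exact_sizes)
        nursing = np.zeros(m)
        nursing[iv] = _sample_truncnorm(rng, oc.nursing_mean, oc.nursing_sd,
                                        int(iv.sum()))
        ab = _sample_lognormal(rng, oc.ab_mean, oc.ab_sd, m)
        age = np.clip(rng.normal(oc.age_mean, oc.age_sd, m), 18.0, 105.0)
        male = _bern(rng, oc.male_prob, m, config.exact_sizes)
        readmit = _bern(rng, oc.readmit_prob, m, config.exact_sizes)
        if arm == "intervention":
            consults = _consult_counts(rng, oc.consult_mean, m,
                                       config.match_means)
        else:
            consults = np.zeros(m, dtype=int)
        if config.match_means:
            los = _rescale_to_mean(los, oc.los_mean)
            nursing[iv] = _rescale_to_mean(nursing[iv], oc.nursing_mean)
            ab = _rescale_to_mean(ab, oc.ab_mean)
        for k, i in enumerate(idx):
            records.append(PatientRecord(
                patient_id=f"{arm[0].upper()}{start_id + i:05d}",
                arm=arm,
                drg_code=str(drg_codes[k]),
                drg_group=group,
                age=float(age[k]),
                sex="M" if male[k] else "F",
                los_days=float(los[k]),
                iv_treated=bool(iv[k]),
                iv_nursing_minutes=float(nursing[k]),
                ab_cost=float(ab[k]),
                n_consults=int(consults[k]),
                readmitted=bool(readmit[k]),
            ))
    records.sort(key=lambda r: r.patient_id)
    return records


def generate_cohort(config: GeneratorConfig) -> tuple[list[PatientRecord], GroundTruth]:
    """Draw a full two-arm, two-group synthetic cohort.

    Returns the records (intervention then control, id-sorted within arm) and
    the :class:`GroundTruth` of generating effects.  Identical config and seed
    give identical records.
    """
    rng = np.random.default_rng(config.seed)
    records = _generate_arm(rng, "intervention", config.n_intervention, config, 0)
    records += _generate_arm(rng, "control", config.n_control, config,
                             config.n_intervention)
    oc = config.outcomes
    truth = GroundTruth(
        p_drg=config.drg1_fraction,
        delta_los={g: oc[g]["control"].los_mean - oc[g]["intervention"].los_mean
                   for g in (1, 2)},
        delta_nursing={g: oc[g]["control"].nursing_mean
                       - oc[g]["intervention"].nursing_mean for g in (1, 2)},
        delta_ab_cost={g: oc[g]["control"].ab_mean - oc[g]["intervention"].ab_mean
                       for g in (1, 2)},
        p_iv={g: oc[g]["intervention"].iv_prob for g in (1, 2)},
        n_audit={g: oc[g]["intervention"].consult_mean for g in (1, 2)},
    )
    return records, truth


def _arm_config(ref, arm: str) -> ArmOutcomeConfig:
    """Outcome config for one reference-table group × arm.

    Individual-level SDs are backed out of the reported 95% CI halfwidths as
    SD = halfwidth / 1.96 × sqrt(n) (nursing over IV-treated patients only).
    """
    z = 1.959963984540054
    if arm == "intervention":
        n, n_iv = ref.n_intervention, ref.iv_intervention
        los_m, los_hw = ref.los_intervention, ref.los_intervention_hw
        nur_m, nur_hw = ref.nursing_intervention, ref.nursing_intervention_hw
        ab_m, ab_hw = ref.ab_intervention, ref.ab_intervention_hw
        age_m, age_hw = ref.age_intervention, ref.age_intervention_hw
        male, readmit = ref.male_intervention, ref.readmit_intervention
    else:
        n, n_iv = ref.n_control, ref.iv_control
        los_m, los_hw = ref.los_control, ref.los_control_hw
        nur_m, nur_hw = ref.nursing_control, ref.nursing_control_hw
        ab_m, ab_hw = ref.ab_control, ref.ab_control_hw
        age_m, age_hw = ref.age_control, ref.age_control_hw
        male, readmit = ref.male_control, ref.readmit_control
    return ArmOutcomeConfig(
        los_mean=los_m, los_sd=los_hw / z * math.sqrt(n),
        iv_prob=n_iv / n,
        nursing_mean=nur_m, nursing_sd=nur_hw / z * math.sqrt(n_iv),
        ab_mean=ab_m, ab_sd=ab_hw / z * math.sqrt(n),
        age_mean=age_m, age_sd=age_hw / z * math.sqrt(n),
        male_prob=male, readmit_prob=readmit,
        consult_mean=ref.n_audit,
    )


def table1_generator_config(n_intervention: int = 114, n_control: int = 357,
                            seed: int = 1234, exact_sizes: bool = True,
                            match_means: bool = True) -> GeneratorConfig:
    """Generator config reproducing the reference urology cohort's table."""
    table = defaults.REFERENCE_TABLE
    drg1_fraction = table[1].n_intervention / (
        table[1].n_intervention + table[2].n_intervention)
    drg1_fraction_control = table[1].n_control / (
        table[1].n_control + table[2].n_control)
    return GeneratorConfig(
        n_intervention=n_intervention,
        n_control=n_control,
        drg1_fraction=drg1_fraction,
        drg1_fraction_control=drg1_fraction_control,
        outcomes={g: {arm: _arm_config(table[g], arm)
                      for arm in ("intervention", "control")}
                  for g in (1, 2)},
        seed=seed,
        exact_sizes=exact_sizes,
        match_means=match_means,
    )


def table1_fixture(seed: int = 1234) -> tuple[list[PatientRecord], GroundTruth]:
    """Fixed-seed cohort whose group summaries reproduce the reference table.

    114 audited patients (70 infection-DRG / 44 other) and 357 historic
    controls (209 / 148); arm × group means of LOS, IV nursing time and
    antibiotic cost match the reference values exactly by construction.
    """
    return generate_cohort(table1_generator_config(seed=seed))
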