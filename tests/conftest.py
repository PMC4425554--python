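"""Shared fixtures: reference parameters, the fixed synthetic cohort, and
session-cached simulation studies (null gating rates, parameter recovery)
used by both the module property tests and the acceptance tests."""

from __future__ import annotations

import numpy as np
import pytest

import stewardcost as sc
from stewardcost import defaults


@pytest.fixture(scope="session")
def baseline_params() -> sc.ModelParameters:
    """Model parameters at the reference study's printed point estimates."""
    return sc.ModelParameters(
        p_drg=70 / 114,
        p_iv=52 / 70,
        delta_los=7.57 - 6.20,
        delta_nursing=251.66 - 178.19,
        delta_ab_cost=0.0,
        c_bed=716.0,
        c_nurse_hour=30.0,
        c_audit=sc.audit_cost_total(defaults.DEFAULT_AUDIT_COSTS),
        n_audit=defaults.N_AUDIT_OVERALL,
        n_patients=114,
    )


@pytest.fixture(scope="session")
def fixture_cohort():
    records, truth = sc.table1_fixture()
    return records, truth


@pytest.fixture(scope="session")
def fixture_arms(fixture_cohort):
    records, _ = fixture_cohort
    intervention = [r for r in records if r.arm == "intervention"]
    control = [r for r in records if r.arm == "control"]
    return intervention, control


@pytest.fixture(scope="session")
def fixture_calibration(fixture_arms):
    intervention, control = fixture_arms
    return sc.extract_parameters(intervention, control,
                                 defaults.DEFAULT_COSTS,
                                 defaults.DEFAULT_AUDIT_COSTS)


def _single_group_config(n: int, seed: int, effect: bool) -> sc.GeneratorConfig:
    """One-group cohort; arms identical when ``effect`` is False, else the
    reference group-1 deltas."""
    control = sc.ArmOutcomeConfig(
        los_mean=7.57, los_sd=4.72, iv_prob=0.80,
        nursing_mean=251.66, nursing_sd=217.8,
        ab_mean=17.42, ab_sd=24.56, readmit_prob=0.12, consult_mean=1.0)
    if effect:
        intervention = sc.ArmOutcomeConfig(
            los_mean=6.20, los_sd=2.60, iv_prob=0.7429,
            nursing_mean=178.19, nursing_sd=150.5,
            ab_mean=13.34, ab_sd=19.38, readmit_prob=0.17, consult_mean=1.11)
    else:
        intervention = sc.ArmOutcomeConfig(
            los_mean=control.los_mean, los_sd=control.los_sd,
            iv_prob=control.iv_prob,
            nursing_mean=control.nursing_mean, nursing_sd=control.nursing_sd,
            ab_mean=control.ab_mean, ab_sd=control.ab_sd,
            readmit_prob=control.readmit_prob, consult_mean=1.11)
    outcomes = {1: {"intervention": intervention, "control": control},
                2: {"intervention": intervention, "control": control}}
    return sc.GeneratorConfig(n_intervention=n, n_control=n,
                              drg1_fraction=1.0, outcomes=outcomes, seed=seed)


@pytest.fixture(scope="session")
def null_gating_rates():
    """Inclusion rates per outcome over 200 null cohorts (n=500/arm).

    Arms are generated from identical distributions, so the gate at
    alpha=0.025 should fire at ~2.5% per outcome.
    """
    outcomes = ("los", "iv_nursing", "ab_cost")
    n_reps = 200
    counts = {o: 0 for o in outcomes}
    for rep in range(n_reps):
        records, _ = sc.generate_cohort(
            _single_group_config(500, seed=10_000 + rep, effect=False))
        gi = [r for r in records if r.arm == "intervention"]
        gc = [r for r in records if r.arm == "control"]
        for outcome in outcomes:
            eff = sc.compare_outcome(gi, gc, outcome, alpha=0.025)
            counts[outcome] += int(eff.included)
    return {o: counts[o] / n_reps for o in outcomes}, n_reps


def _recovery_estimates(n_per_arm: int, n_reps: int, seed0: int):
    """Replicated calibrated deltas on effectful group-1 cohorts."""
    est = {"los": [], "iv_nursing": []}
    for rep in range(n_reps):
        records, _ = sc.generate_cohort(
            _single_group_config(n_per_arm, seed=seed0 + rep, effect=True))
        gi = [r for r in records if r.arm == "intervention"]
        gc = [r for r in records if r.arm == "control"]
        result = sc.extract_parameters(gi, gc, defaults.DEFAULT_COSTS,
                                       defaults.DEFAULT_AUDIT_COSTS)
        params = result.parameters[1]
        if params.delta_los != 0.0:
            est["los"].append(params.delta_los)
        if params.delta_nursing != 0.0:
            est["iv_nursing"].append(params.delta_nursing)
    return est


@pytest.fixture(scope="session")
def recovery_study():
    """Included-delta estimates at two cohort sizes, plus the truths."""
    truth = {"los": 7.57 - 6.20, "iv_nursing": 251.66 - 178.19}
    small = _recovery_estimates(300, n_reps=60, seed0=20_000)
    large = _recovery_estimates(1200, n_reps=30, seed0=30_000)
    return truth, small, large


@pytest.fixture(scope="session")
def reference_psa_spec():
    return sc.uncertainty_from_reference(defaults.REFERENCE_DRG1)


def psa_reference_baseline() -> sc.ModelParameters:
    """The PSA run configuration: infection-DRG share at 100%, audit cost at
    80.26 x the group-1 mean of 1.11 audits/patient, other parameters at the
    reference point estimates."""
    return sc.ModelParameters(
        p_drg=1.0, p_iv=52 / 70,
        delta_los=7.57 - 6.20, delta_nursing=251.66 - 178.19,
        delta_ab_cost=17.42 - 13.34,
        c_bed=716.0, c_nurse_hour=30.0,
        c_audit=80.26, n_audit=1.11, n_patients=114)
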