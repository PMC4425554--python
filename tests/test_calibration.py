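"""Calibration tests: grouping, matching, summaries, testing and gating.

The p-value oracle is a hand-rolled full-enumeration permutation test,
independent of the scipy routines it cross-checks.
"""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import stewardcost as sc
from stewardcost import defaults
from stewardcost.errors import (
    ConfigurationError,
    InsufficientDataError,
    MatchingError,
    ValidationError,
)


def record(**overrides):
    base = dict(patient_id="P1", arm="intervention", drg_code="DBC-INF-01",
                drg_group=1, age=60.0, sex="M", los_days=5.0, iv_treated=True,
                iv_nursing_minutes=120.0, ab_cost=10.0, n_consults=1,
                readmitted=False)
    base.update(overrides)
    return sc.PatientRecord(**base)


def records_with(values, outcome="los", arm="intervention", code="DBC-INF-01"):
    out = []
    for i, v in enumerate(values):
        kw = dict(patient_id=f"{arm}-{i}", arm=arm, drg_code=code,
                  n_consults=1 if arm == "intervention" else 0)
        if outcome == "los":
            kw["los_days"] = v
        elif outcome == "iv_nursing":
            kw["iv_nursing_minutes"] = v
        elif outcome == "ab_cost":
            kw["ab_cost"] = v
        out.append(record(**kw))
    return out


class TestRecordInvariants:
    def test_nursing_minutes_forbidden_without_iv(self):
        with pytest.raises(ValidationError, match="iv_nursing_minutes"):
            record(iv_treated=False, iv_nursing_minutes=30.0)

    def test_nonpositive_los_rejected(self):
        with pytest.raises(ValidationError, match="los_days"):
            record(los_days=0.0)

    @pytest.mark.parametrize("field, value", [
        ("arm", "placebo"), ("sex", "X"), ("drg_group", 3), ("n_consults", -1),
    ])
    def test_enum_and_range_checks(self, field, value):
        with pytest.raises(ValidationError):
            record(**{field: value})


class TestAssignDrgGroup:
    def test_infection_code_is_group_1(self):
        assert sc.assign_drg_group(record(drg_code="INF-01"), {"INF-01"}) == 1

    def test_other_code_is_group_2(self):
        assert sc.assign_drg_group(record(drg_code="ONC-07"), {"INF-01"}) == 2

    def test_empty_code_set_rejected(self):
        with pytest.raises(ValidationError):
            sc.assign_drg_group(record(), set())

    def test_empty_code_rejected(self):
        with pytest.raises(ValidationError):
            sc.assign_drg_group(record(drg_code=""), {"INF-01"})

    def test_reference_cohort_share(self, fixture_calibration):
        """70 of 114 audited patients in the infection group -> 61.40%."""
        p_drg = fixture_calibration.parameters[1].p_drg
        assert round(100 * p_drg, 2) == 61.40


class TestFrequencyMatch:
    def _pool(self, counts):
        out = []
        for code, n in counts.items():
            group = 1 if "INF" in code else 2
            out += records_with(np.linspace(2, 9, n), arm="control", code=code)
            for r in out[-n:]:
                assert r.drg_code == code
        return [sc.PatientRecord(**{**r.__dict__, "drg_group":
                                    1 if "INF" in r.drg_code else 2})
                for r in out]

    def test_identical_distribution_full_target_returns_pool(self):
        pool = self._pool({"DBC-INF-01": 6, "DBC-ONC-01": 4})
        ref = pool
        matched = sc.frequency_match(pool, ref, n_target=len(pool), seed=0)
        assert sorted(r.patient_id for r in matched) == sorted(
            r.patient_id for r in pool)

    def test_exact_even_split(self):
        pool = self._pool({"DBC-INF-01": 100, "DBC-ONC-01": 100})
        ref = self._pool({"DBC-INF-01": 5, "DBC-ONC-01": 5})
        matched = sc.frequency_match(pool, ref, n_target=10, seed=1)
        codes = [r.drg_code for r in matched]
        assert codes.count("DBC-INF-01") == 5
        assert codes.count("DBC-ONC-01") == 5

    def test_largest_remainder_apportionment(self):
        """61.4% / 38.6% over 357 -> 219 vs 138 by largest remainder."""
        ref = self._pool({"DBC-INF-01": 614, "DBC-ONC-01": 386})
        pool = self._pool({"DBC-INF-01": 500, "DBC-ONC-01": 500})
        matched = sc.frequency_match(pool, ref, n_target=357, seed=2)
        codes = [r.drg_code for r in matched]
        assert codes.count("DBC-INF-01") == 219
        assert codes.count("DBC-ONC-01") == 138

    def test_missing_code_listed_in_error(self):
        ref = self._pool({"DBC-INF-01": 3, "DBC-INF-02": 3})
        pool = self._pool({"DBC-INF-01": 10})
        with pytest.raises(MatchingError, match="DBC-INF-02"):
            sc.frequency_match(pool, ref, n_target=5, seed=0)

    def test_seed_reproducibility(self):
        pool = self._pool({"DBC-INF-01": 50, "DBC-ONC-01": 50})
        ref = self._pool({"DBC-INF-01": 7, "DBC-ONC-01": 3})
        a = sc.frequency_match(pool, ref, n_target=20, seed=42)
        b = sc.frequency_match(pool, ref, n_target=20, seed=42)
        assert [r.patient_id for r in a] == [r.patient_id for r in b]

    @given(n1=st.integers(2, 40), n2=st.integers(2, 40),
           target=st.integers(1, 30))
    @settings(max_examples=30, deadline=None)
    def test_counts_within_one_of_real_targets(self, n1, n2, target):
        pool = self._pool({"DBC-INF-01": 40, "DBC-ONC-01": 40})
        ref = self._pool({"DBC-INF-01": n1, "DBC-ONC-01": n2})
        matched = sc.frequency_match(pool, ref, n_target=target, seed=5)
        assert len(matched) == target
        codes = [r.drg_code for r in matched]
        for code, n_ref in (("DBC-INF-01", n1), ("DBC-ONC-01", n2)):
            ideal = target * n_ref / (n1 + n2)
            assert abs(codes.count(code) - ideal) < 1


class TestSummarizeGroup:
    def test_constant_values(self):
        s = sc.summarize_group(records_with([5, 5, 5, 5]), "los")
        assert (s.n, s.mean, s.ci95_halfwidth) == (4, 5.0, 0.0)

    def test_t_based_halfwidth(self):
        s = sc.summarize_group(records_with([1, 2, 3]), "los")
        assert s.mean == pytest.approx(2.0)
        assert s.ci95_halfwidth == pytest.approx(2.4842, abs=1e-4)

    def test_iv_nursing_uses_iv_denominator_only(self):
        recs = records_with([100.0, 200.0], outcome="iv_nursing")
        recs.append(record(patient_id="x", iv_treated=False,
                           iv_nursing_minutes=0.0))
        s = sc.summarize_group(recs, "iv_nursing")
        assert s.n == 2
        assert s.mean == 150.0

    def test_single_record_mean_rejected(self):
        with pytest.raises(InsufficientDataError):
            sc.summarize_group(records_with([4.0]), "los")

    def test_proportion_outcome(self):
        recs = [record(patient_id=str(i), sex="M" if i < 3 else "F")
                for i in range(4)]
        s = sc.summarize_group(recs, "sex")
        assert s.is_proportion and s.mean == 0.75

    def test_fixture_mean_within_own_ci(self, fixture_arms):
        """The synthetic group-1 LOS mean sits inside its own 95% CI around
        the generating value."""
        intervention, _ = fixture_arms
        g1 = [r for r in intervention if r.drg_group == 1]
        s = sc.summarize_group(g1, "los")
        assert abs(s.mean - 6.20) <= max(s.ci95_halfwidth, 1e-9)


def _perm_welch_p(x, y):
    """Full-enumeration permutation p-value of the Welch t statistic."""

    def welch_t(a, b):
        a, b = np.asarray(a, float), np.asarray(b, float)
        va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
        return abs(a.mean() - b.mean()) / math.sqrt(va + vb)

    pooled = list(x) + list(y)
    n1 = len(x)
    observed = welch_t(x, y)
    hits = total = 0
    for idx in itertools.combinations(range(len(pooled)), n1):
        mask = set(idx)
        a = [pooled[i] for i in idx]
        b = [pooled[i] for i in range(len(pooled)) if i not in mask]
        total += 1
        if welch_t(a, b) >= observed - 1e-12:
            hits += 1
    return hits / total


def _perm_mw_p(x, y):
    """Full-enumeration permutation p-value of the Mann-Whitney U statistic."""
    pooled = list(x) + list(y)
    n1, n2 = len(x), len(y)
    mu = n1 * n2 / 2.0

    def u_stat(a, b):
        return sum(1.0 for xi in a for yj in b if xi > yj)

    observed = abs(u_stat(x, y) - mu)
    hits = total = 0
    for idx in itertools.combinations(range(len(pooled)), n1):
        mask = set(idx)
        a = [pooled[i] for i in idx]
        b = [pooled[i] for i in range(len(pooled)) if i not in mask]
        total += 1
        if abs(u_stat(a, b) - mu) >= observed - 1e-12:
            hits += 1
    return hits / total


class TestCompareOutcome:
    def test_identical_samples_not_included(self):
        gi = records_with([3, 4, 5, 6])
        gc = records_with([6, 5, 4, 3], arm="control")
        for test in ("welch_t", "mann_whitney", "log_rank"):
            eff = sc.compare_outcome(gi, gc, "los", test)
            assert eff.delta == 0.0 and not eff.included

    def test_gate_follows_alpha(self):
        gi = records_with([1, 2, 3, 4, 5])
        gc = records_with([6, 7, 8, 9, 10], arm="control")
        tight = sc.compare_outcome(gi, gc, "los", "welch_t", alpha=1e-6)
        loose = sc.compare_outcome(gi, gc, "los", "welch_t", alpha=0.999999)
        assert not tight.included and loose.included
        assert tight.p_value == loose.p_value

    def test_delta_is_control_minus_intervention(self):
        gi = records_with([2.0, 2.0, 2.0, 2.2])
        gc = records_with([5.0, 5.0, 5.0, 5.2], arm="control")
        eff = sc.compare_outcome(gi, gc, "los", "welch_t")
        assert eff.delta == pytest.approx(3.0)

    def test_mismatched_test_and_outcome_rejected(self):
        gi = records_with([1.5, 2.5, 3.0])
        gc = records_with([2.0, 3.0, 4.0], arm="control")
        with pytest.raises(ConfigurationError):
            sc.compare_outcome(gi, gc, "los", "chi_square")
        with pytest.raises(ConfigurationError):
            sc.compare_outcome(gi, gc, "los", "not_a_test")

    def test_empty_arm_rejected(self):
        with pytest.raises(InsufficientDataError):
            sc.compare_outcome([], records_with([1.0, 2.0], arm="control"),
                               "los", "welch_t")

    @pytest.mark.parametrize("x, y", [
        ([1.2, 3.4, 5.1, 7.8, 2.9], [2.2, 4.0, 6.6, 9.9, 10.4]),
        ([5.0, 6.5, 7.2, 8.8], [4.1, 4.9, 5.5, 6.1, 6.9, 7.7]),
    ])
    def test_mann_whitney_matches_enumeration(self, x, y):
        gi = records_with(x)
        gc = records_with(y, arm="control")
        eff = sc.compare_outcome(gi, gc, "los", "mann_whitney")
        assert eff.p_value == pytest.approx(_perm_mw_p(x, y), abs=1e-9)

    @pytest.mark.parametrize("x, y", [
        ([1.2, 3.4, 5.1, 7.8, 2.9, 4.4], [2.2, 4.0, 6.6, 9.9, 10.4, 8.1]),
        ([5.0, 6.5, 7.2, 8.8, 9.1], [4.1, 4.9, 5.5, 6.1, 6.9, 7.7]),
    ])
    def test_welch_t_near_permutation_oracle(self, x, y):
        """The t-distribution p approximates the exact permutation p at
        small n (they are different procedures; agreement is approximate)."""
        gi = records_with(x)
        gc = records_with(y, arm="control")
        eff = sc.compare_outcome(gi, gc, "los", "welch_t")
        assert eff.p_value == pytest.approx(_perm_welch_p(x, y), abs=0.15)

    def test_readmission_chi_square(self):
        gi = [record(patient_id=str(i), readmitted=i < 2) for i in range(20)]
        gc = [record(patient_id=f"c{i}", arm="control", n_consults=0,
                     readmitted=i < 10) for i in range(20)]
        eff = sc.compare_outcome(gi, gc, "readmission", "chi_square")
        assert eff.delta == pytest.approx(0.4)
        assert 0.0 < eff.p_value < 0.05


class TestExtractParameters:
    def test_identical_arms_leave_only_audit_cost(self):
        gi = [record(patient_id=f"i{i}", los_days=3 + i % 4,
                     iv_nursing_minutes=100 + i, ab_cost=9 + i % 3)
              for i in range(12)]
        gi += [record(patient_id=f"i2{i}", drg_code="DBC-ONC-01", drg_group=2,
                      los_days=4 + i % 3, iv_nursing_minutes=90 + i)
               for i in range(12)]
        gc = [sc.PatientRecord(**{**r.__dict__, "arm": "control",
                                  "patient_id": "c" + r.patient_id,
                                  "n_consults": 0}) for r in gi]
        result = sc.extract_parameters(gi, gc, defaults.DEFAULT_COSTS,
                                       defaults.DEFAULT_AUDIT_COSTS)
        for params in result.parameters.values():
            assert params.delta_los == 0.0
            assert params.delta_nursing == 0.0
            assert params.delta_ab_cost == 0.0
            assert sc.per_patient_net_benefit(params) == pytest.approx(
                -params.c_audit * params.n_audit)

    def test_fixture_group2_contributes_audit_share_only_via_los(
            self, fixture_calibration):
        """No significant LOS/nursing change in the underlying-disease group."""
        params2 = fixture_calibration.parameters[2]
        assert params2.delta_los == 0.0
        assert params2.delta_nursing == 0.0

    def test_fixture_group1_recovers_reference_deltas(self, fixture_calibration):
        params1 = fixture_calibration.parameters[1]
        assert params1.delta_los == pytest.approx(7.57 - 6.20, abs=1e-9)
        assert params1.delta_nursing == pytest.approx(251.66 - 178.19, abs=1e-9)
        assert params1.p_iv == pytest.approx(52 / 70)
        assert params1.n_audit == pytest.approx(1.11, abs=0.01)

    def test_empty_arm_rejected(self):
        with pytest.raises(InsufficientDataError):
            sc.extract_parameters([], [record()], defaults.DEFAULT_COSTS,
                                  defaults.DEFAULT_AUDIT_COSTS)

    def test_combined_net_benefit_sums_group_brackets(self, fixture_calibration):
        res = fixture_calibration
        manual = 0.0
        for params in res.parameters.values():
            manual += params.p_drg * (
                params.delta_los * params.c_bed
                + params.p_iv * params.delta_nursing * params.c_nurse_hour / 60
                + params.delta_ab_cost)
        manual -= res.parameters[1].c_audit * res.n_audit_overall
        assert res.combined_per_patient_net_benefit() == pytest.approx(manual)
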