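"""Caliper volumes, percent change, Mann-Whitney, Grubbs, growth reporting."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from fltquant import (
    CohortTable,
    DegenerateNormalizationError,
    ValidationError,
    caliper_volume,
    generate_growth_cohort,
    grubbs_critical_value,
    grubbs_outlier,
    growth_report,
    mann_whitney,
    normalize_to_vehicle,
    percent_change,
)


def enumeration_mann_whitney_p(a, b):
    """Exact two-tailed p by enumerating every assignment of the pooled values."""
    a, b = list(a), list(b)
    pooled = a + b
    n1 = len(a)
    u_obs = sum(1 for x in a for y in b if x > y) + 0.5 * sum(
        1 for x in a for y in b if x == y
    )
    u_min_obs = min(u_obs, n1 * len(b) - u_obs)
    count = total = 0
    for idx in itertools.combinations(range(len(pooled)), n1):
        ga = [pooled[i] for i in idx]
        gb = [pooled[i] for i in range(len(pooled)) if i not in idx]
        u = sum(1 for x in ga for y in gb if x > y) + 0.5 * sum(
            1 for x in ga for y in gb if x == y
        )
        if min(u, n1 * len(gb) - u) <= u_min_obs + 1e-12:
            count += 1
        total += 1
    return count / total


lengths = st.floats(min_value=0.0, max_value=50.0, allow_nan=False)


class TestCaliperVolume:
    def test_sphere_case(self):
        assert caliper_volume(2.0, 2.0) == pytest.approx(4 * math.pi / 3, abs=1e-9)

    def test_zero_length(self):
        assert caliper_volume(0.0, 5.0) == 0.0

    def test_hand_substitution(self):
        assert caliper_volume(6.0, 4.0) == pytest.approx(20 * math.pi, abs=1e-9)

    def test_negative_rejected(self):
        with pytest.raises(ValidationError):
            caliper_volume(-1.0, 2.0)

    @given(lengths, lengths)
    def test_symmetry(self, l1, l2):
        assert caliper_volume(l1, l2) == pytest.approx(caliper_volume(l2, l1), rel=1e-12)

    @given(lengths, lengths, st.floats(0.1, 3.0))
    def test_cubic_homogeneity(self, l1, l2, k):
        assert caliper_volume(k * l1, k * l2) == pytest.approx(
            k**3 * caliper_volume(l1, l2), rel=1e-9, abs=1e-9
        )


class TestPercentChange:
    def test_no_change(self):
        assert percent_change(100.0, 100.0) == 0.0

    @pytest.mark.parametrize("current,expected", [(149.1, 49.1), (67.8, -32.2)])
    def test_signed_arithmetic(self, current, expected):
        assert percent_change(100.0, current) == pytest.approx(expected)

    def test_inverse_composition(self):
        b, pct = 137.0, 42.0
        current = b * (1 + pct / 100)
        assert percent_change(b, current) == pytest.approx(pct, abs=1e-9)

    def test_nonpositive_baseline_rejected(self):
        with pytest.raises(ValidationError):
            percent_change(0.0, 10.0)


def _cohort_from_pct(day, arm_values, baseline=100.0):
    """Two-timepoint cohort whose day-``day`` percent changes are prescribed."""
    rows = []
    arms = list(arm_values)
    for arm, values in arm_values.items():
        for i, pct in enumerate(values):
            vol0 = baseline
            volT = baseline * (1 + pct / 100)
            for d, v in [(0, vol0), (day, volT)]:
                length = (6 * v / math.pi) ** (1 / 3)
                rows.append(
                    {"subject_id": f"{arm}{i}", "arm": arm, "day": d,
                     "L1": length, "L2": length}
                )
    return CohortTable(records=pd.DataFrame(rows), arms=arms)


class TestNormalizeToVehicle:
    def test_treated_equal_to_vehicle_mean_is_one(self):
        cohort = _cohort_from_pct(10, {"vehicle": [40, 60], "treated": [50]})
        out = normalize_to_vehicle(cohort, "vehicle", 10)
        assert out[out["arm"] == "treated"]["normalized"].iloc[0] == pytest.approx(1.0)

    def test_vehicle_self_normalization_mean_one(self):
        cohort = _cohort_from_pct(10, {"vehicle": [20, 40, 90]})
        out = normalize_to_vehicle(cohort, "vehicle", 10)
        assert out["normalized"].mean() == pytest.approx(1.0)

    def test_half_vehicle_mean(self):
        cohort = _cohort_from_pct(10, {"vehicle": [50.0], "treated": [25.0]})
        out = normalize_to_vehicle(cohort, "vehicle", 10)
        assert out[out["arm"] == "treated"]["normalized"].iloc[0] == pytest.approx(0.5)

    def test_zero_vehicle_mean_rejected(self):
        cohort = _cohort_from_pct(10, {"vehicle": [0.0], "treated": [25.0]})
        with pytest.raises(DegenerateNormalizationError):
            normalize_to_vehicle(cohort, "vehicle", 10)


class TestMannWhitney:
    def test_fully_separated_groups(self):
        r = mann_whitney([1, 2, 3], [4, 5, 6])
        assert r.u_statistic == 0.0
        assert r.p_value == pytest.approx(0.100)
        assert r.method == "exact"

    def test_identical_groups_not_significant(self):
        r = mann_whitney([1, 2, 3], [1, 2, 3])
        assert r.method == "asymptotic"  # ties fall through to the approximation
        assert r.p_value > 0.4

    @pytest.mark.parametrize("n1,n2", [(2, 3), (3, 3), (4, 4), (3, 7), (5, 5)])
    def test_exact_p_matches_full_enumeration(self, n1, n2, rng):
        for _ in range(5):
            a = rng.permutation(np.arange(1.0, n1 + n2 + 1))[:n1]
            b = np.setdiff1d(np.arange(1.0, n1 + n2 + 1), a)
            r = mann_whitney(a, b)
            assert r.method == "exact"
            assert r.p_value == pytest.approx(enumeration_mann_whitney_p(a, b), abs=1e-12)

    def test_large_groups_use_asymptotic(self, rng):
        a, b = rng.normal(size=30), rng.normal(0.5, 1, size=30)
        r = mann_whitney(a, b)
        assert r.method == "asymptotic"
        import scipy.stats

        ref = scipy.stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        assert r.p_value == pytest.approx(ref.pvalue, abs=0.005)

    def test_empty_group_rejected(self):
        with pytest.raises(ValidationError):
            mann_whitney([], [1.0])


class TestGrubbs:
    def test_symmetric_small_sample_no_outlier(self):
        r = grubbs_outlier([1, 2, 3], alpha=0.05)
        assert r.outlier_index is None

    def test_flagged_extreme_value(self):
        r = grubbs_outlier([1, 1, 1, 1, 10], alpha=0.05)
        assert r.outlier_index == 4
        assert r.g_statistic == pytest.approx(7.2 / 4.024922, abs=1e-4)
        assert r.critical_value == pytest.approx(1.715, abs=0.005)

    def test_published_critical_values(self):
        assert grubbs_critical_value(5, 0.05) == pytest.approx(1.715, abs=0.005)
        assert grubbs_critical_value(10, 0.05) == pytest.approx(2.290, abs=0.005)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValidationError):
            grubbs_outlier([1.0, 1.0, 1.0])
        with pytest.raises(ValidationError):
            grubbs_outlier([1.0, 2.0])


class TestGrowthReport:
    def test_single_arm_has_no_comparisons(self):
        cohort = generate_growth_cohort(seed=5, arms=[("vehicle", 10.0, 5.0)], n_per_arm=4)
        report = growth_report(cohort)
        assert report.comparisons.empty
        assert not report.summary.empty

    def test_identical_arms_rarely_significant(self):
        n_sig = 0
        n_seeds = 60
        for seed in range(n_seeds):
            cohort = generate_growth_cohort(
                seed=seed,
                arms=[("a", 10.0, 10.0), ("b", 10.0, 10.0)],
                n_per_arm=5,
                n_assessments=3,
            )
            report = growth_report(cohort)
            final = report.comparisons[report.comparisons["day"] == 9]
            n_sig += int((final["p_value"] < 0.05).any())
        assert n_sig <= 0.10 * n_seeds + 2

    def test_strong_effect_detected(self):
        n_sig = 0
        n_seeds = 30
        for seed in range(n_seeds):
            cohort = generate_growth_cohort(
                seed=seed,
                arms=[("vehicle", 50.0, 10.0), ("combination", -10.0, 10.0)],
                n_per_arm=5,
                n_assessments=3,
            )
            report = growth_report(cohort)
            final = report.comparisons[report.comparisons["day"] == 9]
            n_sig += int((final["p_value"] < 0.05).all())
        assert n_sig >= 0.9 * n_seeds

    def test_grubbs_screening_excludes_extreme_subject(self):
        cohort = _cohort_from_pct(
            10, {"a": [10, 11, 12, 13, 300], "b": [10, 11, 12, 13, 14]}
        )
        report = growth_report(cohort, grubbs=True)
        assert len(report.excluded) >= 1
        assert "a4" in set(report.excluded["subject_id"])


class TestCohortTableValidation:
    def test_duplicate_subject_day_rejected(self):
        df = pd.DataFrame(
            {"subject_id": ["s1", "s1"], "arm": ["a", "a"], "day": [0, 0],
             "L1": [2.0, 2.0], "L2": [2.0, 2.0]}
        )
        with pytest.raises(ValidationError):
            CohortTable(records=df, arms=["a"])

    def test_volume_recomputed_when_absent(self):
        df = pd.DataFrame(
            {"subject_id": ["s1"], "arm": ["a"], "day": [0], "L1": [2.0], "L2": [2.0]}
        )
        t = CohortTable(records=df, arms=["a"])
        assert t.records["volume"].iloc[0] == pytest.approx(caliper_volume(2.0, 2.0))
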