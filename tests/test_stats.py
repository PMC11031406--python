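import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from liquidmrd.errors import ValidationError
from liquidmrd.io import OutcomeRecord, Timepoint
from liquidmrd.stats import (
    CapGrade,
    exact_binomial_ci,
    fisher_exact_2x2,
    grade_regression,
    km_estimate,
    logrank_test,
    months_from_days,
    survival_by_ctdna,
    wilcoxon_rank_sum,
)
from liquidmrd.status import Evaluability, Pattern, Status, TimepointCall, PatientTrajectory


class TestGradeRegression:
    @pytest.mark.parametrize(
        "pct,grade,pcr,mpr",
        [
            (0, CapGrade.G0, True, True),
            (5, CapGrade.G1, False, True),
            (10, CapGrade.G1, False, True),   # boundary in lower band
            (11, CapGrade.G2, False, False),
            (50, CapGrade.G2, False, False),  # boundary in lower band
            (55, CapGrade.G3, False, False),
            (100, CapGrade.G3, False, False),
        ],
    )
    def test_bands(self, pct, grade, pcr, mpr):
        r = grade_regression(pct)
        assert (r.cap_grade, r.pcr, r.mpr) == (grade, pcr, mpr)

    def test_out_of_range_rejected(self):
        for bad in (-1, 101):
            with pytest.raises(ValidationError):
                grade_regression(bad)

    @given(st.floats(min_value=0, max_value=100, allow_nan=False))
    def test_total_function_and_partition(self, pct):
        r = grade_regression(pct)
        assert r.cap_grade in CapGrade
        assert r.pcr == (r.cap_grade is CapGrade.G0)
        assert r.mpr == (pct <= 10.0)


class TestKmEstimate:
    def test_no_events_flat_curve(self):
        curve = km_estimate([1, 2, 3, 4, 5], [False] * 5)
        assert curve.event_times.size == 0
        assert curve.median is None
        assert curve.survival_at(100.0) == 1.0

    def test_hand_calculation(self):
        # times {2(event), 1(censored), 3(censored), 5(event), 4(censored)}
        # risk sets: t=2 -> n=4, d=1 -> S=3/4; t=5 -> n=1, d=1 -> S=0
        curve = km_estimate([2, 1, 3, 5, 4], [True, False, False, True, False])
        assert list(curve.event_times) == [2, 5]
        assert curve.survival[0] == pytest.approx(0.75)
        assert curve.survival[1] == pytest.approx(0.0)
        assert curve.median == 5

    def test_all_events_at_one(self):
        curve = km_estimate([1, 1, 1], [True, True, True])
        assert curve.survival[0] == 0.0
        assert curve.median == 1

    def test_matches_empirical_sf_without_censoring(self):
        rng = np.random.default_rng(3)
        t = rng.exponential(5, 40).round(3)
        curve = km_estimate(t, [True] * 40)
        for q in (1.0, 3.0, 8.0):
            assert curve.survival_at(q) == pytest.approx(np.mean(t > q))

    def test_matches_lifelines_reference(self):
        lifelines = pytest.importorskip("lifelines")
        rng = np.random.default_rng(11)
        t = rng.exponential(10, 30)
        e = rng.random(30) < 0.7
        kmf = lifelines.KaplanMeierFitter()
        kmf.fit(t, e)
        curve = km_estimate(t, e)
        for tt in curve.event_times:
            assert curve.survival_at(tt) == pytest.approx(
                float(kmf.predict(tt)), abs=1e-9
            )

    def test_ci_brackets_estimate_within_unit_interval(self):
        rng = np.random.default_rng(5)
        t = rng.exponential(10, 25)
        e = rng.random(25) < 0.8
        curve = km_estimate(t, e)
        assert np.all(curve.ci_lower >= 0) and np.all(curve.ci_upper <= 1)
        mask = (curve.survival > 0) & (curve.survival < 1)
        assert np.all(curve.ci_lower[mask] <= curve.survival[mask])
        assert np.all(curve.ci_upper[mask] >= curve.survival[mask])

    def test_survival_nonincreasing(self):
        rng = np.random.default_rng(9)
        t = rng.exponential(4, 50)
        e = rng.random(50) < 0.6
        curve = km_estimate(t, e)
        assert np.all(np.diff(curve.survival) <= 1e-12)

    def test_negative_time_rejected(self):
        with pytest.raises(ValidationError):
            km_estimate([-1.0], [True])

    def test_months_conversion(self):
        assert months_from_days(30.4375) == pytest.approx(1.0)


class TestLogrank:
    def test_identical_groups_chi2_zero(self):
        t = [1, 2, 3, 4, 1, 2, 3, 4]
        e = [True] * 8
        g = [0, 0, 0, 0, 1, 1, 1, 1]
        res = logrank_test(t, e, g)
        assert res.chi_square == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_three_groups_df_two(self):
        t = [1, 2, 3, 4, 5, 6]
        e = [True] * 6
        g = ["UD", "UD", "NEG", "NEG", "POS", "POS"]
        assert logrank_test(t, e, g).df == 2

    def test_relabeling_invariance(self):
        rng = np.random.default_rng(2)
        t = rng.exponential(1, 30)
        e = rng.random(30) < 0.8
        g = rng.integers(0, 2, 30)
        a = logrank_test(t, e, g)
        b = logrank_test(t, e, 1 - g)
        assert a.chi_square == pytest.approx(b.chi_square)

    def test_single_group_rejected(self):
        with pytest.raises(ValidationError):
            logrank_test([1, 2], [True, True], [0, 0])

    def test_matches_lifelines_with_ties(self):
        lifelines_stats = pytest.importorskip("lifelines.statistics")
        rng = np.random.default_rng(8)
        t = np.round(rng.exponential(5, 40))  # induce ties
        e = rng.random(40) < 0.7
        g = rng.integers(0, 2, 40)
        mine = logrank_test(t, e, g)
        ref = lifelines_stats.multivariate_logrank_test(t, g, e)
        assert mine.chi_square == pytest.approx(ref.test_statistic, rel=1e-9)
        assert mine.p_value == pytest.approx(ref.p_value, rel=1e-9)


class TestExactBinomialCi:
    def test_zero_successes_lower_bound_zero(self):
        lo, hi = exact_binomial_ci(0, 10)
        assert lo == 0.0
        assert hi == pytest.approx(1 - 0.025 ** (1 / 10))

    def test_all_successes_upper_bound_one(self):
        lo, hi = exact_binomial_ci(10, 10)
        assert hi == 1.0

    def test_x_above_n_rejected(self):
        with pytest.raises(ValidationError):
            exact_binomial_ci(11, 10)

    @pytest.mark.parametrize("x,n", [(3, 14), (6, 15), (10, 32), (1, 7)])
    def test_endpoints_satisfy_tail_equations(self, x, n):
        # defining property: binomial tails equal alpha/2 at the endpoints
        lo, hi = exact_binomial_ci(x, n)
        if 0 < x:
            assert sps.binom.sf(x - 1, n, lo) == pytest.approx(0.025, abs=1e-9)
        if x < n:
            assert sps.binom.cdf(x, n, hi) == pytest.approx(0.025, abs=1e-9)


class TestFisherExact:
    def test_balanced_table_p_one(self):
        assert fisher_exact_2x2([[5, 5], [5, 5]]) == pytest.approx(1.0)

    def test_matches_enumeration_oracle(self):
        # hand-enumerated hypergeometric tail for [[1,9],[9,1]]
        table = [[1, 9], [9, 1]]
        n, row1, col1 = 20, 10, 10
        pmf = lambda a: (math.comb(col1, a) * math.comb(n - col1, row1 - a) / math.comb(n, row1))
        expected = sum(pmf(a) for a in range(0, 11) if pmf(a) <= pmf(1) * (1 + 1e-7))
        assert fisher_exact_2x2(table) == pytest.approx(expected)
        assert fisher_exact_2x2(table) == pytest.approx(
            float(sps.fisher_exact(table).pvalue)
        )

    def test_degenerate_table_rejected(self):
        with pytest.raises(ValidationError):
            fisher_exact_2x2([[0, 0], [0, 0]])

    def test_negative_cell_rejected(self):
        with pytest.raises(ValidationError):
            fisher_exact_2x2([[1, -1], [2, 3]])

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.integers(min_value=0, max_value=12), min_size=4, max_size=4))
    def test_matches_scipy_everywhere(self, cells):
        a, b, c, d = cells
        if a + b + c + d == 0:
            return
        table = [[a, b], [c, d]]
        assert fisher_exact_2x2(table) == pytest.approx(
            float(sps.fisher_exact(table).pvalue), abs=1e-10
        )


class TestWilcoxon:
    def test_identical_samples_p_one(self):
        assert wilcoxon_rank_sum([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)

    def test_full_enumeration_small_case(self):
        # a={1,2,3} vs b={4,5,6}: of C(6,3)=20 rank assignments only the two
        # extremes are as or more extreme -> two-sided exact p = 2/20 = 0.1
        assert wilcoxon_rank_sum([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValidationError):
            wilcoxon_rank_sum([], [1.0])

    def test_large_sample_uses_tie_corrected_normal(self):
        rng = np.random.default_rng(4)
        a = np.round(rng.normal(0, 1, 15), 1)
        b = np.round(rng.normal(0.5, 1, 15), 1)
        mine = wilcoxon_rank_sum(a, b)
        ref = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        assert mine == pytest.approx(float(ref.pvalue))


def _traj(patient_id, statuses, evaluability=Evaluability.EVALUABLE, pattern=Pattern.MIXED):
    tps = (Timepoint.BASELINE, Timepoint.D14, Timepoint.POST_ICI, Timepoint.PREOP, Timepoint.POSTOP)
    calls = tuple(
        TimepointCall(patient_id, tp, s, 1 if s is Status.POSITIVE else 0, 0.0)
        for tp, s in zip(tps, statuses)
    )
    return PatientTrajectory(patient_id, calls, evaluability, pattern)


def _outcome(patient_id, rfs, event):
    return OutcomeRecord(patient_id, "A", True, rfs, event, rfs, event)


P, N = Status.POSITIVE, Status.NEGATIVE


class TestSurvivalByCtdna:
    def test_groups_and_ud_stratum(self):
        trajectories = [
            _traj("P1", [P, P, P, P, P]),
            _traj("P2", [P, P, N, N, N]),
            _traj("P3", [N, N, N, N, N], evaluability=Evaluability.UD, pattern=Pattern.UD),
        ]
        outcomes = [_outcome("P1", 5, True), _outcome("P2", 30, False), _outcome("P3", 30, False)]
        two = survival_by_ctdna(trajectories, outcomes, Timepoint.POST_ICI, "RFS")
        assert set(two.groups) == {"DETECTED", "UNDETECTED"}
        three = survival_by_ctdna(trajectories, outcomes, Timepoint.POST_ICI, "RFS", three_way=True)
        assert set(three.groups) == {"DETECTED", "UNDETECTED", "UD"}
        assert three.logrank.df == 2

    def test_single_group_skipped_with_warning(self):
        trajectories = [_traj("P1", [P, P, P, P, P])]
        outcomes = [_outcome("P1", 5, True)]
        cmp_ = survival_by_ctdna(trajectories, outcomes, Timepoint.PREOP, "RFS")
        assert cmp_.logrank is None
        assert "skipped" in cmp_.warning

    def test_ud_only_no_test(self):
        trajectories = [
            _traj("P1", [N, N, N, N, N], evaluability=Evaluability.UD, pattern=Pattern.UD)
        ]
        outcomes = [_outcome("P1", 30, False)]
        cmp_ = survival_by_ctdna(trajectories, outcomes, Timepoint.PREOP, "RFS", three_way=True)
        assert set(cmp_.groups) == {"UD"}
        assert cmp_.logrank is None

    def test_bad_endpoint_rejected(self):
        with pytest.raises(ValidationError):
            survival_by_ctdna([], [], Timepoint.PREOP, "PFS")

    def test_simulated_hazard_separation(self):
        # planted hazard ratio 3: detected group must fare worse
        rng = np.random.default_rng(12)
        trajectories, outcomes = [], []
        for i in range(60):
            detected = i % 2 == 0
            pid = f"P{i}"
            trajectories.append(_traj(pid, [P, P, P if detected else N, P if detected else N, P if detected else N]))
            rate = (3.0 if detected else 1.0) / 24.0
            t = float(rng.exponential(1 / rate))
            outcomes.append(_outcome(pid, min(t, 36.0), t <= 36.0))
        cmp_ = survival_by_ctdna(trajectories, outcomes, Timepoint.POSTOP, "RFS")
        med_det = cmp_.groups["DETECTED"].median
        med_undet = cmp_.groups["UNDETECTED"].median
        assert med_det is not None
        assert med_undet is None or med_undet > med_det
        assert cmp_.logrank.p_value < 0.05
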