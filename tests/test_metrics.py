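"""Error summaries, Wilcoxon signed-rank, method comparison, calibration, kappa."""

import itertools

import numpy as np
import pytest
from sklearn.metrics import cohen_kappa_score

from dentage import (
    CoefficientTable,
    PredictionOutcome,
    calibration_slope,
    compare_methods,
    error_summary,
    weighted_kappa,
    wilcoxon_signed_rank,
)
from dentage.stages import STAGES, StageCode

from conftest import balanced_stage_cohort, identifiable_truth_table
from dentage.simulate import attach_additive_ages


def outcomes_from_errors(errors):
    return [
        PredictionOutcome(f"s{i}", 10.0 - e, float(e)) for i, e in enumerate(errors)
    ]


class TestErrorSummary:
    @pytest.mark.parametrize(
        "errors,me,mae,rmse",
        [
            ([1, -1], 0.0, 1.0, 1.0),
            ([0, 0, 0], 0.0, 0.0, 0.0),
            ([3, -1, 2, -2, 0], 0.4, 1.6, np.sqrt(18 / 5)),
        ],
    )
    def test_hand_arithmetic(self, errors, me, mae, rmse):
        s = error_summary(outcomes_from_errors(errors), ci_reps=50, seed=0)
        assert s.me == pytest.approx(me, abs=1e-12)
        assert s.mae == pytest.approx(mae, abs=1e-12)
        assert s.rmse == pytest.approx(rmse, abs=1e-12)

    def test_all_zero_errors_flag_degenerate_wilcoxon(self):
        s = error_summary(outcomes_from_errors([0, 0, 0]), ci_reps=50, seed=0)
        assert "wilcoxon_degenerate" in s.flags
        assert s.wilcoxon_p == 1.0

    def test_empty_errors_and_single_subject(self):
        with pytest.raises(ValueError):
            error_summary([])
        s = error_summary(outcomes_from_errors([0.5]), ci_reps=50, seed=0)
        assert "single_subject" in s.flags
        assert np.isnan(s.me_sd)

    def test_summary_invariants_on_random_vectors(self):
        """mae >= |me|, rmse >= mae, rmse^2 = me^2 + pop-var, CI brackets RMSE,
        and the summary is permutation invariant."""
        rng = np.random.default_rng(11)
        for _ in range(50):
            errors = rng.normal(rng.normal(), rng.uniform(0.1, 2.0), size=40)
            s = error_summary(outcomes_from_errors(errors), ci_reps=200, seed=1)
            assert s.mae >= abs(s.me) - 1e-12
            assert s.rmse >= s.mae - 1e-12
            assert s.rmse**2 == pytest.approx(
                s.me**2 + np.var(errors), abs=1e-10
            )
            assert s.rmse_ci[0] <= s.rmse <= s.rmse_ci[1]
            perm = error_summary(
                outcomes_from_errors(rng.permutation(errors)), ci_reps=200, seed=1
            )
            assert perm.me == pytest.approx(s.me, abs=1e-12)
            assert perm.rmse == pytest.approx(s.rmse, abs=1e-12)


def brute_force_wilcoxon_p(diffs):
    """Exact two-sided p by enumerating all 2^n sign assignments of the ranks."""
    from scipy.stats import rankdata

    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    ranks = rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    stats = np.array(
        [
            float(np.sum(ranks[np.array(signs, dtype=bool)]))
            for signs in itertools.product([False, True], repeat=len(ranks))
        ]
    )
    cdf = np.mean(stats <= w_obs + 1e-9)
    sf = np.mean(stats >= w_obs - 1e-9)
    return min(1.0, 2.0 * min(cdf, sf))


class TestWilcoxon:
    def test_identical_pairs_degenerate(self):
        res = wilcoxon_signed_rank([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.degenerate and res.p_value == 1.0
        assert res.n_zeros == 3

    def test_three_positive_differences_exact(self):
        """All-positive diffs at n=3: p = 2/8 over the sign enumeration."""
        res = wilcoxon_signed_rank([1.0, 2.0, 3.0])
        assert res.method == "exact"
        assert res.p_value == pytest.approx(0.25, abs=1e-12)

    def test_zero_differences_dropped_and_counted(self):
        res = wilcoxon_signed_rank([0.0, 1.0, 2.0, 3.0])
        assert res.n_zeros == 1 and res.n_used == 3

    @pytest.mark.parametrize("seed", range(6))
    def test_exact_path_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        d = np.round(rng.normal(0.3, 1.0, size=rng.integers(4, 13)), 2)
        d = d[d != 0]
        if d.size == 0:
            return
        res = wilcoxon_signed_rank(d)
        assert res.method == "exact"
        assert res.p_value == pytest.approx(brute_force_wilcoxon_p(d), abs=1e-12)

    def test_normal_approximation_close_to_exact(self):
        """Approximation path agrees with exact enumeration within 0.02 at n=12."""
        from dentage import metrics

        rng = np.random.default_rng(123)
        for _ in range(10):
            d = rng.normal(0.4, 1.0, size=12)
            exact = wilcoxon_signed_rank(d)
            assert exact.method == "exact"
            old = metrics.EXACT_N_MAX
            try:
                metrics.EXACT_N_MAX = 0  # force the approximation path
                approx = wilcoxon_signed_rank(d)
            finally:
                metrics.EXACT_N_MAX = old
            assert approx.method == "normal_approx"
            assert abs(approx.p_value - exact.p_value) < 0.02

    def test_agrees_with_scipy_exact(self):
        from scipy.stats import wilcoxon as scipy_wilcoxon

        rng = np.random.default_rng(5)
        d = rng.normal(0.5, 1.0, size=15)
        ours = wilcoxon_signed_rank(d)
        ref = scipy_wilcoxon(d, method="exact")
        assert ours.p_value == pytest.approx(ref.pvalue, abs=1e-12)


class TestCompareMethods:
    def test_identical_tables_all_zero_and_degenerate(self):
        table = identifiable_truth_table(seed=3)
        cohort = attach_additive_ages(
            balanced_stage_cohort(30, seed=4), table, noise_sd=0.5, seed=5
        )
        cmp = compare_methods(cohort, table, table, ci_reps=100, seed=6)
        g = cmp.groups["M+F"]
        assert g.me_diff == 0.0 and g.mae_diff == 0.0
        assert "wilcoxon_degenerate" in g.flags

    def test_single_cell_perturbation_shifts_me_diff(self):
        """Adding +0.5 y to one stage-H cell of table B lowers B's errors by 0.5
        for subjects with that tooth at H, so me_A - me_B = +0.5."""
        table_a = identifiable_truth_table(seed=7)
        bumped = dict(table_a.entries)
        bumped[("M", 34, StageCode.H)] += 0.5
        bumped[("F", 34, StageCode.H)] += 0.5
        table_b = CoefficientTable(bumped, name="bumped")
        records = []
        base = balanced_stage_cohort(40, seed=8)
        from dentage import Cohort, DentitionRecord

        for r in base:
            stages = dict(r.stages)
            stages[34] = StageCode.H
            records.append(DentitionRecord(r.subject_id, r.sex, r.chron_age, stages))
        cohort = attach_additive_ages(
            Cohort(records), table_a, noise_sd=0.3, seed=9
        )
        cmp = compare_methods(cohort, table_a, table_b, ci_reps=100, seed=10)
        assert cmp.groups["M+F"].me_diff == pytest.approx(0.5, abs=1e-10)

    def test_matches_loop_computed_statistics(self):
        table_a = identifiable_truth_table(seed=11)
        table_b = identifiable_truth_table(seed=12)
        cohort = attach_additive_ages(
            balanced_stage_cohort(200, seed=13), table_a, noise_sd=1.0, seed=14
        )
        cmp = compare_methods(cohort, table_a, table_b, ci_reps=100, seed=15)
        from dentage import estimate_age

        ea, eb = [], []
        for r in cohort:
            ea.append(r.chron_age - estimate_age(table_a, r))
            eb.append(r.chron_age - estimate_age(table_b, r))
        ea, eb = np.array(ea), np.array(eb)
        g = cmp.groups["M+F"]
        assert g.me_diff == pytest.approx(float((ea - eb).mean()), abs=1e-12)
        assert g.mae_diff == pytest.approx(
            float((np.abs(ea) - np.abs(eb)).mean()), abs=1e-12
        )
        assert g.rmse_a == pytest.approx(float(np.sqrt((ea**2).mean())), abs=1e-12)

    def test_antisymmetry_under_table_swap(self):
        table_a = identifiable_truth_table(seed=21)
        table_b = identifiable_truth_table(seed=22)
        cohort = attach_additive_ages(
            balanced_stage_cohort(80, seed=23), table_a, noise_sd=0.8, seed=24
        )
        ab = compare_methods(cohort, table_a, table_b, ci_reps=100, seed=25)
        ba = compare_methods(cohort, table_b, table_a, ci_reps=100, seed=25)
        for grp in ab.groups:
            assert ab.groups[grp].me_diff == pytest.approx(-ba.groups[grp].me_diff)
            assert ab.groups[grp].mae_diff == pytest.approx(-ba.groups[grp].mae_diff)

    def test_empty_cohort_errors(self):
        from dentage import Cohort

        t = identifiable_truth_table(seed=1)
        with pytest.raises(ValueError):
            compare_methods(Cohort([]), t, t)


class TestCalibrationSlope:
    def test_perfect_calibration(self):
        chron = [4.0, 8.0, 12.0, 16.0]
        assert calibration_slope(chron, chron) == pytest.approx((1.0, 0.0), abs=1e-12)

    def test_exact_linear_case(self):
        chron = np.array([5.0, 7.5, 10.0, 14.0])
        slope, intercept = calibration_slope(chron, 2 * chron + 1)
        assert (slope, intercept) == pytest.approx((2.0, 1.0), abs=1e-10)

    def test_matches_normal_equations_on_noisy_pairs(self):
        rng = np.random.default_rng(31)
        x = rng.uniform(4, 16, size=60)
        y = 0.95 * x + 0.3 + rng.normal(0, 0.8, size=60)
        slope, intercept = calibration_slope(x, y)
        sxx = np.sum((x - x.mean()) ** 2)
        sxy = np.sum((x - x.mean()) * (y - y.mean()))
        assert slope == pytest.approx(sxy / sxx, abs=1e-10)
        assert intercept == pytest.approx(y.mean() - (sxy / sxx) * x.mean(), abs=1e-10)

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError):
            calibration_slope([1, 2], [1, 2])
        with pytest.raises(ValueError):
            calibration_slope([5, 5, 5], [1, 2, 3])


def stages_from(chars):
    return [StageCode(c) for c in chars]


class TestWeightedKappa:
    def test_identical_ratings_give_one(self):
        r = stages_from("DDEEFFGH")
        for w in ("linear", "quadratic"):
            assert weighted_kappa(r, r, w).kappa == pytest.approx(1.0)

    def test_hand_contingency(self):
        """10-pair 3-level contingency: linear k = 1 - 0.625/1.1 = 0.43182."""
        r1 = stages_from("DDEEFFDEFD")
        r2 = stages_from("DEEEFDDEFF")
        assert weighted_kappa(r1, r2, "linear").kappa == pytest.approx(
            0.4318181818, abs=1e-9
        )
        assert weighted_kappa(r1, r2, "quadratic").kappa == pytest.approx(
            0.3076923077, abs=1e-9
        )

    @pytest.mark.parametrize("weighting", ["linear", "quadratic"])
    @pytest.mark.parametrize("seed", [0, 1])
    def test_agrees_with_sklearn(self, weighting, seed):
        rng = np.random.default_rng(seed)
        a = rng.integers(0, 9, size=200)
        b = np.clip(a + rng.integers(-2, 3, size=200), 0, 8)
        r1 = [STAGES[i] for i in a]
        r2 = [STAGES[i] for i in b]
        ref = cohen_kappa_score(a, b, labels=list(range(9)), weights=weighting)
        assert weighted_kappa(r1, r2, weighting).kappa == pytest.approx(ref, abs=1e-12)

    def test_independent_ratings_near_zero(self):
        rng = np.random.default_rng(42)
        a = rng.integers(0, 9, size=20000)
        b = rng.integers(0, 9, size=20000)
        res = weighted_kappa([STAGES[i] for i in a], [STAGES[i] for i in b], "linear")
        assert abs(res.kappa) < 0.02

    def test_two_level_scale_reduces_to_unweighted(self):
        rng = np.random.default_rng(7)
        a = rng.integers(0, 2, size=300)
        b = (a + (rng.random(300) < 0.2)) % 2
        pair = [(StageCode.D, StageCode.E)[i] for i in a], [
            (StageCode.D, StageCode.E)[i] for i in b
        ]
        unweighted = cohen_kappa_score(a, b)
        for w in ("linear", "quadratic"):
            assert weighted_kappa(*pair, w).kappa == pytest.approx(unweighted, abs=1e-12)

    def test_constant_rater_flagged(self):
        r1 = [StageCode.D] * 5
        r2 = [StageCode.D] * 5
        res = weighted_kappa(r1, r2)
        assert np.isnan(res.kappa) and "no_variation" in res.flags
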