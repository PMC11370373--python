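"""Logistic kernel-machine score test: null fit, statistic, Davies null."""

import numpy as np
import pytest

from kernelds import (
    DistanceMatrix,
    KernelMatrix,
    SimulationConfig,
    fit_null_logistic,
    gaussian_kernel,
    null_weights,
    run_score_test,
    score_statistic,
    simulate_unit,
    weighted_chisq_pvalue,
)


def _kernel(entries, rho=1.0):
    return KernelMatrix(entries=np.asarray(entries, dtype=float), rho=rho)


class TestFitNullLogistic:
    def test_intercept_only_closed_form(self):
        y = np.array([1, 1, 1, 0, 0, 0, 0, 0], dtype=float)
        fit = fit_null_logistic(y, np.ones((8, 1)))
        np.testing.assert_allclose(fit.fitted_probs, 3 / 8, atol=1e-8)

    def test_constant_outcome_errors(self):
        with pytest.raises(ValueError, match="both levels"):
            fit_null_logistic(np.ones(6), np.ones((6, 1)))

    def test_rank_deficient_design_errors(self):
        X = np.ones((6, 2))  # duplicated intercept
        y = np.array([0, 1, 0, 1, 0, 1], dtype=float)
        with pytest.raises(ValueError, match="rank"):
            fit_null_logistic(y, X)

    def test_two_by_two_table_odds_ratio(self):
        # binary covariate: fitted log-odds-ratio equals log(ad/bc)
        a, b, c, d = 6, 4, 3, 7  # x=1: a cases, b controls; x=0: c cases, d controls
        x = np.array([1] * (a + b) + [0] * (c + d), dtype=float)
        y = np.array([1] * a + [0] * b + [1] * c + [0] * d, dtype=float)
        X = np.column_stack([np.ones_like(x), x])
        fit = fit_null_logistic(y, X)
        assert fit.coefficients[1] == pytest.approx(np.log(a * d / (b * c)), abs=1e-6)

    def test_agrees_with_statsmodels_glm(self, rng):
        import statsmodels.api as sm

        X = np.column_stack([np.ones(40), rng.normal(size=40)])
        y = (rng.random(40) < 0.5).astype(float)
        fit = fit_null_logistic(y, X)
        ref = sm.GLM(y, X, family=sm.families.Binomial()).fit()
        np.testing.assert_allclose(fit.coefficients, ref.params, atol=1e-6)

    def test_separation_triggers_ridge_fallback(self):
        x = np.array([0, 0, 0, 1, 1, 1], dtype=float)
        y = x.copy()  # perfectly separated
        X = np.column_stack([np.ones(6), x])
        fit = fit_null_logistic(y, X)
        assert fit.separation
        assert np.all(np.isfinite(fit.coefficients))


class TestScoreStatistic:
    def test_zero_when_outcome_equals_fit(self):
        y = np.array([1, 1, 0, 0], dtype=float)
        fit = fit_null_logistic(y, np.ones((4, 1)))
        fit.fitted_probs = y.copy()
        assert score_statistic(y, fit, _kernel(np.eye(4))) == 0.0

    def test_identity_kernel_gives_residual_sum_of_squares(self):
        y = np.array([1, 0, 1, 0], dtype=float)
        fit = fit_null_logistic(y, np.ones((4, 1)))
        q = score_statistic(y, fit, _kernel(np.eye(4)))
        assert q == pytest.approx(np.sum((y - 0.5) ** 2))

    def test_linear_in_kernel_scale(self, rng):
        y = np.array([1, 0, 1, 0, 1, 0], dtype=float)
        fit = fit_null_logistic(y, np.ones((6, 1)))
        A = rng.normal(size=(6, 6))
        K = (A + A.T) / 2
        q1 = score_statistic(y, fit, _kernel(K))
        q3 = score_statistic(y, fit, _kernel(3 * K, rho=1.0))
        assert q3 == pytest.approx(3 * q1)


class TestNullWeights:
    def test_weights_sum_to_projected_trace(self):
        y = np.array([1, 1, 0, 0, 1, 0], dtype=float)
        fit = fit_null_logistic(y, np.ones((6, 1)))
        K = _kernel(np.eye(6))
        w = null_weights(fit, K)
        mu = fit.fitted_probs
        V = np.diag(mu * (1 - mu))
        X = fit.design
        P0 = V - V @ X @ np.linalg.solve(X.T @ V @ X, X.T @ V)
        assert w.sum() == pytest.approx(np.trace(P0), abs=1e-10)

    def test_zero_kernel_gives_zero_weights(self):
        y = np.array([1, 0, 1, 0], dtype=float)
        fit = fit_null_logistic(y, np.ones((4, 1)))
        assert np.all(null_weights(fit, _kernel(np.zeros((4, 4)))) == 0)

    def test_invariant_to_simultaneous_permutation(self, rng):
        n = 8
        y = np.array([1, 0] * 4, dtype=float)
        A = rng.normal(size=(n, n))
        K = A @ A.T
        fit = fit_null_logistic(y, np.ones((n, 1)))
        w = null_weights(fit, _kernel(K))
        perm = rng.permutation(n)
        fit_p = fit_null_logistic(y[perm], np.ones((n, 1)))
        w_p = null_weights(fit_p, _kernel(K[np.ix_(perm, perm)]))
        np.testing.assert_allclose(np.sort(w), np.sort(w_p), atol=1e-10)


class TestWeightedChisqPvalue:
    def test_chi_square_one_closed_form(self):
        assert weighted_chisq_pvalue(3.841459, [1.0]) == pytest.approx(0.05, abs=1e-6)

    def test_half_chi_square_two_is_exponential(self):
        # 0.5*chi2_2 ~ Exponential(1): P(X > ln 20) = 0.05
        assert weighted_chisq_pvalue(np.log(20), [0.5, 0.5]) == pytest.approx(
            0.05, abs=1e-6
        )

    def test_zero_statistic_gives_one(self):
        assert weighted_chisq_pvalue(0.0, [0.3, 0.2]) == 1.0

    def test_all_zero_weights_give_one(self):
        assert weighted_chisq_pvalue(1.0, [0.0, 0.0]) == 1.0

    def test_unequal_weights_against_monte_carlo(self, rng):
        w = np.array([2.0, 1.0, 0.25])
        draws = rng.chisquare(1, size=(200000, 3)) @ w
        for q in (1.0, 3.0, 8.0):
            assert weighted_chisq_pvalue(q, w) == pytest.approx(
                (draws > q).mean(), abs=0.005
            )

    def test_negative_statistic_errors(self):
        with pytest.raises(ValueError):
            weighted_chisq_pvalue(-1.0, [1.0])


class TestRunScoreTest:
    def test_deterministic(self, small_unit):
        r1 = run_score_test(small_unit, "sc")
        r2 = run_score_test(small_unit, "sc")
        assert r1.p_value == r2.p_value and r1.statistic == r2.statistic

    def test_group_relabel_invariance(self, small_unit):
        from dataclasses import replace

        r = run_score_test(small_unit, "pb")
        flipped = replace(small_unit, outcome=1 - small_unit.outcome)
        r_flip = run_score_test(flipped, "pb")
        assert r.p_value == pytest.approx(r_flip.p_value, abs=1e-10)

    def test_degenerate_unit_gets_p_one(self):
        from kernelds.density import TestUnit as ExpressionUnit

        unit = ExpressionUnit(
            feature_id="g",
            cluster_id="c",
            subject_ids=["a", "b", "c", "d"],
            values=[np.full(5, 2.0)] * 4,
            outcome=np.array([0, 0, 1, 1]),
        )
        res = run_score_test(unit, "sc")
        assert res.p_value == 1.0 and res.degenerate

    def test_mean_shift_detected_by_pb_variant(self):
        cfg = SimulationConfig(
            subjects_per_group=8, cells_per_subject_per_cluster=100, de_shift=2.5
        )
        rejections = 0
        for s in range(20):
            unit, _ = simulate_unit("DE", cfg, unit_seed=300 + s)
            if run_score_test(unit, "pb").p_value < 0.05:
                rejections += 1
        assert rejections >= 15  # strong shift at 8+8 subjects

    def test_permutation_null_uniformity(self):
        # permutation-null option: exact enumeration at 4+4 is well calibrated
        from scipy import stats

        cfg = SimulationConfig(subjects_per_group=4, cells_per_subject_per_cluster=50)
        pvals = [
            run_score_test(
                simulate_unit("null", cfg, unit_seed=5000 + s)[0],
                "sc",
                grid_size=256,
                null_method="permutation",
            ).p_value
            for s in range(120)
        ]
        rej = np.mean(np.array(pvals) <= 0.05)
        assert 0.0 <= rej <= 0.11
        assert stats.kstest(pvals, "uniform").pvalue > 0.01


class TestAsymptoticRegime:
    def test_permutation_matches_davies_at_moderate_n(self, rng):
        # at n = 50 the weighted-chi-square null matches the permutation
        # distribution of Q in Kolmogorov distance
        n = 50
        y = np.zeros(n)
        y[:25] = 1.0
        pts = rng.normal(size=n)
        d = np.abs(pts[:, None] - pts[None, :])
        np.fill_diagonal(d, 0.0)
        D = DistanceMatrix(entries=d, subject_ids=[str(i) for i in range(n)])
        from kernelds import median_bandwidth

        rho, _ = median_bandwidth(D)
        K = gaussian_kernel(D, rho)
        fit = fit_null_logistic(y, np.ones((n, 1)))
        w = null_weights(fit, K)
        q_perm = []
        for _ in range(3000):
            yp = rng.permutation(y)
            fp = fit_null_logistic(yp, np.ones((n, 1)))
            q_perm.append(score_statistic(yp, fp, K))
        q_perm = np.sort(q_perm)
        davies_cdf = np.array([1 - weighted_chisq_pvalue(q, w) for q in q_perm[::60]])
        emp_cdf = np.searchsorted(q_perm, q_perm[::60], side="right") / len(q_perm)
        assert np.max(np.abs(davies_cdf - emp_cdf)) <= 0.05
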