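import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import minimize

from biosig.sparse import (average_logistic_loss, fit_intercept_only,
                           fit_l1_logistic, fit_path, kkt_residual,
                           lambda_max, soft_threshold, standardize_columns)
from conftest import random_two_class_instance


def oracle_objective(X, y, lam):
    """Independent minimizer of the penalized objective: split w = u - v
    with u, v >= 0, which turns the L1 term into a smooth bound-constrained
    problem solved by L-BFGS-B.  Written apart from the production solver."""
    n, p = X.shape

    def fg(z):
        u, v, c = z[:p], z[p:2 * p], z[2 * p]
        w = u - v
        m = y * (X @ w + c)
        loss = np.mean(np.logaddexp(0.0, -m))
        s = 1.0 / (1.0 + np.exp(np.clip(m, -500, 500)))
        g = -(y * s) / n
        gw = X.T @ g
        grad = np.concatenate([gw + lam, -gw + lam, [g.sum()]])
        return loss + lam * (u.sum() + v.sum()), grad

    res = minimize(fg, np.zeros(2 * p + 1), jac=True, method="L-BFGS-B",
                   bounds=[(0, None)] * (2 * p) + [(None, None)],
                   options={"maxiter": 5000, "ftol": 1e-16, "gtol": 1e-12})
    u, v, c = res.x[:p], res.x[p:2 * p], res.x[2 * p]
    w = u - v
    return average_logistic_loss(w, c, X, y) + lam * np.abs(w).sum()


class TestLoss:
    def test_zero_weights_give_log_two(self, rng):
        X = rng.standard_normal((7, 3))
        y = np.where(rng.random(7) < 0.5, 1.0, -1.0)
        assert average_logistic_loss(np.zeros(3), 0.0, X, y) == pytest.approx(
            np.log(2.0), abs=1e-12)

    @pytest.mark.parametrize("X,y,w,c,expected", [
        (np.array([[1.0]]), np.array([1.0]), np.array([1.0]), 0.0,
         np.log1p(np.exp(-1.0))),
        (np.array([[1.0, 0.0], [0.0, 1.0]]), np.array([1.0, -1.0]),
         np.array([2.0, -2.0]), 0.0, np.log1p(np.exp(-2.0))),
    ])
    def test_closed_forms(self, X, y, w, c, expected):
        assert average_logistic_loss(w, c, X, y) == pytest.approx(expected,
                                                                  abs=1e-12)

    def test_stable_for_huge_margins(self):
        X = np.array([[1e4], [-1e4]])
        y = np.array([1.0, -1.0])
        v = average_logistic_loss(np.array([10.0]), 0.0, X, y)
        assert np.isfinite(v) and v >= 0.0

    def test_nan_rejected(self):
        with pytest.raises(ValueError):
            average_logistic_loss(np.array([np.nan]), 0.0,
                                  np.array([[1.0]]), np.array([1.0]))


class TestSoftThreshold:
    def test_examples(self):
        np.testing.assert_allclose(soft_threshold(np.array([3.0, -1.0, 0.5]), 1.0),
                                   [2.0, 0.0, 0.0])
        np.testing.assert_allclose(soft_threshold(np.array([-2.5]), 1.0), [-1.5])

    @given(st.lists(st.floats(-1e6, 1e6), min_size=1, max_size=20),
           st.floats(0, 1e6))
    @settings(deadline=None, max_examples=50)
    def test_shrinks_toward_zero(self, vals, t):
        v = np.array(vals)
        out = soft_threshold(v, t)
        assert (np.abs(out) <= np.abs(v) + 1e-12).all()
        assert (out * v >= 0).all()          # never flips sign
        np.testing.assert_array_equal(soft_threshold(v, 0.0), v)

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError):
            soft_threshold(np.array([1.0]), -0.1)


class TestInterceptAndLambdaMax:
    def test_intercept_closed_forms(self):
        assert fit_intercept_only(np.array([1, 1, -1, -1])) == 0.0
        assert fit_intercept_only(np.array([1, 1, 1, -1])) == pytest.approx(
            np.log(3.0))
        with pytest.raises(ValueError):
            fit_intercept_only(np.array([1, 1]))

    def test_lambda_max_hand_value(self):
        y = np.array([1.0, 1.0, -1.0, -1.0])
        X = np.array([[1.0], [1.0], [-1.0], [-1.0]])
        assert lambda_max(X, y) == pytest.approx(0.5)

    def test_lambda_max_scales_linearly(self, rng):
        X, y = random_two_class_instance(rng)
        assert lambda_max(3.5 * X, y) == pytest.approx(3.5 * lambda_max(X, y))

    def test_fit_above_lambda_max_is_empty(self, rng):
        X = rng.standard_normal((20, 5))
        y = np.where(rng.random(20) < 0.5, 1.0, -1.0)
        Xs, _, _ = standardize_columns(X)
        lm = lambda_max(Xs, y)
        fit = fit_l1_logistic(Xs, y, lm * 1.001, standardize=False)
        assert fit.support.size == 0
        assert fit.c == pytest.approx(fit_intercept_only(y), abs=1e-6)


class TestSolverAgainstOracle:
    def test_printed_toy_instance(self):
        X = np.array([[1, 0], [2, 0], [1.5, 0.1],
                      [-1, 0], [-2, 0], [-1.5, -0.1]], dtype=float)
        y = np.array([1, 1, 1, -1, -1, -1], dtype=float)
        lam = 0.1
        fit = fit_l1_logistic(X, y, lam, standardize=False)
        assert fit.converged
        assert fit.objective <= oracle_objective(X, y, lam) + 1e-6

    def test_fifty_random_instances(self, rng):
        for _ in range(50):
            X, y = random_two_class_instance(rng)
            Xs, _, _ = standardize_columns(X)
            lam = lambda_max(Xs, y) * rng.uniform(0.05, 0.5)
            fit = fit_l1_logistic(Xs, y, lam, standardize=False)
            assert fit.converged
            assert kkt_residual(fit, Xs, y) <= 1e-8 * max(1.0, lam)
            assert fit.objective <= oracle_objective(Xs, y, lam) + 1e-6

    def test_nonpositive_lambda_rejected(self, rng):
        X, y = random_two_class_instance(rng)
        with pytest.raises(ValueError):
            fit_l1_logistic(X, y, 0.0)

    def test_agrees_with_liblinear(self, rng):
        """Cross-check against scikit-learn's L1 logistic regression:
        liblinear minimizes C*sum(loss) + ||w||_1, i.e. C = 1/(n*lam)."""
        from sklearn.linear_model import LogisticRegression
        for _ in range(10):
            X, y = random_two_class_instance(rng, n_max=40, p_max=6)
            Xs, _, _ = standardize_columns(X)
            lam = lambda_max(Xs, y) * 0.3
            fit = fit_l1_logistic(Xs, y, lam, standardize=False)
            skl = LogisticRegression(l1_ratio=1.0, C=1.0 / (len(y) * lam),
                                     solver="liblinear", tol=1e-10,
                                     max_iter=10000).fit(Xs, (y > 0))
            w, c = skl.coef_[0], skl.intercept_[0]
            obj_skl = average_logistic_loss(w, c, Xs, y) + lam * np.abs(w).sum()
            assert fit.objective <= obj_skl + 1e-5


class TestKKTResidual:
    def test_zero_at_trivial_optimum(self, rng):
        X, y = random_two_class_instance(rng)
        Xs, _, _ = standardize_columns(X)
        lm = lambda_max(Xs, y)
        fit = fit_l1_logistic(Xs, y, lm * 1.1, standardize=False)
        assert kkt_residual(fit, Xs, y) <= 1e-8

    def test_perturbation_raises_residual(self, rng):
        X, y = random_two_class_instance(rng, n_max=30, p_max=4)
        Xs, _, _ = standardize_columns(X)
        lam = lambda_max(Xs, y) * 0.2
        fit = fit_l1_logistic(Xs, y, lam, standardize=False)
        if fit.support.size == 0:
            pytest.skip("no active coordinate to perturb at this penalty")
        j = fit.support[0]
        fit.w = fit.w.copy()
        fit.w[j] += 1.0
        assert kkt_residual(fit, Xs, y) > lam / 10


class TestPath:
    def test_all_above_lambda_max_empty(self, rng):
        X, y = random_two_class_instance(rng)
        Xs, _, _ = standardize_columns(X)
        lm = lambda_max(Xs, y)
        path = fit_path(Xs, y, [lm * 1.01, lm * 2, lm * 5], standardize=False)
        assert all(f.support.size == 0 for f in path.fits)

    def test_support_grows_from_sparse_end(self, rng):
        X = rng.standard_normal((40, 8))
        y = np.where(rng.random(40) < 0.5, 1.0, -1.0)
        Xs, _, _ = standardize_columns(X)
        lm = lambda_max(Xs, y)
        grid = np.linspace(0.1, 1.0, 10) * lm
        path = fit_path(Xs, y, grid, standardize=False)
        # decreasing-lambda order: first fit (largest lambda) at most as
        # large as the last (smallest lambda)
        assert len(path.fits[0].support) <= len(path.fits[-1].support)

    def test_warm_start_matches_cold_start(self, rng):
        X = rng.standard_normal((35, 6))
        y = np.where(rng.random(35) < 0.5, 1.0, -1.0)
        Xs, _, _ = standardize_columns(X)
        lm = lambda_max(Xs, y)
        grid = np.linspace(0.08, 1.0, 8) * lm
        path = fit_path(Xs, y, grid, standardize=False)
        for fit in path.fits:
            cold = fit_l1_logistic(Xs, y, fit.lam, standardize=False)
            assert abs(cold.objective - fit.objective) <= 1e-6

    def test_scale_invariance_with_standardization(self, rng):
        X = rng.standard_normal((30, 4)) * np.array([1.0, 10.0, 0.1, 100.0])
        y = np.where(rng.random(30) < 0.5, 1.0, -1.0)
        f1 = fit_l1_logistic(X, y, 0.05, standardize=True)
        f2 = fit_l1_logistic(X * 7.0, y, 0.05, standardize=True)
        np.testing.assert_allclose(f1.w, f2.w, atol=1e-6)
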