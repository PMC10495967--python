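import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from penbench import (
    PenaltySpec,
    adaptive_weights,
    fit_adaptive_lasso,
    fit_elastic_net,
    fit_lasso,
    fit_scad,
    kkt_residual,
    scad_penalty,
    scad_penalty_derivative,
    soft_threshold,
)
from penbench.solvers import (
    _cd_gram,
    _lqa_scad,
    LQA_DROP_TOL,
    gram,
    standardize,
)

from conftest import random_instances


def _ols(X, y):
    Xi = np.column_stack([np.ones(len(y)), X])
    return np.linalg.lstsq(Xi, y, rcond=None)[0][1:]


def _orthonormalize(X):
    """Columns centered and scaled so that X'X/n = I exactly."""
    n = X.shape[0]
    Q, _ = np.linalg.qr(X - X.mean(axis=0))
    Xo = Q * np.sqrt(n)
    return Xo


# ---------------------------------------------------------------------------
# penalty primitives
# ---------------------------------------------------------------------------

class TestSoftThreshold:
    @pytest.mark.parametrize("z,t,expected", [(3, 1, 2), (0.5, 1, 0), (-3, 1, -2)])
    def test_examples(self, z, t, expected):
        assert soft_threshold(z, t) == expected

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError):
            soft_threshold(1.0, -0.5)

    @given(st.floats(-1e6, 1e6), st.floats(0, 1e6))
    @settings(max_examples=50, deadline=None)
    def test_shrinkage_properties(self, z, t):
        out = soft_threshold(z, t)
        assert abs(out) <= abs(z) + 1e-12
        assert out == 0 or np.sign(out) == np.sign(z)
        assert soft_threshold(-z, t) == -out


class TestScadPenalty:
    def test_three_branches(self):
        assert scad_penalty(0.5, 1.0, 3.7) == pytest.approx(0.5)
        assert scad_penalty(5.0, 1.0, 3.7) == pytest.approx(2.35)
        assert scad_penalty(2.0, 1.0, 3.7) == pytest.approx((14.8 - 4 - 1) / 5.4)

    def test_derivative_branches(self):
        assert scad_penalty_derivative(0.5, 1.0, 3.7) == pytest.approx(1.0)
        assert scad_penalty_derivative(5.0, 1.0, 3.7) == pytest.approx(0.0)
        assert scad_penalty_derivative(2.0, 1.0, 3.7) == pytest.approx(1.7 / 2.7)
        # odd in beta
        assert scad_penalty_derivative(-2.0, 1.0, 3.7) == pytest.approx(-1.7 / 2.7)

    @pytest.mark.parametrize("lam", [0.3, 1.0, 2.5])
    def test_continuity_at_knots(self, lam):
        a = 3.7
        for knot in (lam, a * lam):
            eps = 1e-9 * knot
            left = scad_penalty(knot - eps, lam, a)
            right = scad_penalty(knot + eps, lam, a)
            assert abs(left - right) < 1e-7 * max(1.0, knot)
        # exact knot values: lambda^2 at |b|=lam, (a+1)lam^2/2 at |b|=a*lam
        assert scad_penalty(lam, lam, a) == pytest.approx(lam**2)
        assert scad_penalty(a * lam, lam, a) == pytest.approx((a + 1) * lam**2 / 2)

    def test_invalid_a_rejected(self):
        with pytest.raises(ValueError):
            scad_penalty(1.0, 1.0, 2.0)
        with pytest.raises(ValueError):
            scad_penalty_derivative(1.0, 1.0, 1.5)

    @given(st.floats(0, 20), st.floats(0.01, 3), st.floats(2.1, 10))
    @settings(max_examples=50, deadline=None)
    def test_penalty_monotone_and_bounded(self, b, lam, a):
        p = scad_penalty(b, lam, a)
        assert 0 <= p <= (a + 1) * lam**2 / 2 + 1e-12
        assert scad_penalty(b + 0.1, lam, a) >= p - 1e-12


class TestAdaptiveWeights:
    def test_examples(self):
        assert np.allclose(adaptive_weights([2, 0.5], 1.0), [0.5, 2])
        assert np.allclose(adaptive_weights([1, 1], 2.7), [1, 1])
        assert np.allclose(adaptive_weights([4.0], 0.5), [0.5])

    def test_zero_initial_estimate_capped(self):
        w = adaptive_weights([0.0, 1.0], 1.0)
        assert w[0] == 1e8 and w[1] == 1.0

    def test_invalid_gamma(self):
        with pytest.raises(ValueError):
            adaptive_weights([1.0], 0.0)


# ---------------------------------------------------------------------------
# lasso
# ---------------------------------------------------------------------------

class TestLasso:
    def test_unpenalized_limit_is_ols(self, small_regression):
        X, y, _ = small_regression
        res = fit_lasso(X, y, 0.0)
        assert np.allclose(res.coefficients, _ols(X, y), atol=1e-6)

    def test_lambda_max_gives_null_model(self, small_regression):
        X, y, _ = small_regression
        Xs, ys, *_ = standardize(X, y)
        lam_max = np.abs(Xs.T @ ys).max() / len(ys)
        res = fit_lasso(X, y, lam_max * 1.000001)
        assert np.all(res.coefficients == 0)
        # strictly below lambda_max at least one coefficient activates
        res2 = fit_lasso(X, y, lam_max * 0.99)
        assert np.any(res2.coefficients != 0)

    def test_orthonormal_design_closed_form(self, rng):
        X = _orthonormalize(rng.standard_normal((48, 5)))
        beta = np.array([2.0, -1.0, 0.0, 0.5, 0.0])
        y = X @ beta + 0.3 * rng.standard_normal(48)
        ols = _ols(X, y)
        for lam in (0.05, 0.3, 0.8):
            res = fit_lasso(X, y, lam)
            assert np.allclose(res.coefficients, soft_threshold(ols, lam),
                               atol=1e-8)

    def test_sparsity_endpoints(self, small_regression):
        X, y, _ = small_regression
        Xs, ys, *_ = standardize(X, y)
        lam_max = np.abs(Xs.T @ ys).max() / len(ys)
        assert np.count_nonzero(fit_lasso(X, y, lam_max).coefficients) == 0
        assert np.count_nonzero(fit_lasso(X, y, 0.0).coefficients) == X.shape[1]

    def test_nonfinite_input_rejected(self):
        X = np.ones((10, 2))
        X[0, 0] = np.nan
        with pytest.raises(ValueError):
            fit_lasso(X, np.ones(10), 0.1)

    def test_matches_glmnet_reference(self, tmp_path):
        """Independent cross-check of the lasso path against R glmnet."""
        import shutil
        import subprocess

        if shutil.which("Rscript") is None:
            pytest.skip("Rscript not available")
        rng = np.random.default_rng(7)
        X = rng.standard_normal((40, 6))
        beta = np.array([2.0, 0, -1, 0, 0, 0.5])
        y = X @ beta + 0.5 * rng.standard_normal(40)
        np.savetxt(tmp_path / "X.csv", X, delimiter=",")
        np.savetxt(tmp_path / "y.csv", y, delimiter=",")
        rcode = (
            f'X <- as.matrix(read.csv("{tmp_path}/X.csv", header=FALSE)); '
            f'y <- scan("{tmp_path}/y.csv"); '
            'suppressMessages(library(glmnet)); '
            'f <- glmnet(X, y, alpha=1, lambda=c(0.3, 0.15, 0.05), '
            'standardize=TRUE, thresh=1e-12); '
            'cat(as.numeric(as.matrix(coef(f))), sep=",")'
        )
        out = subprocess.run(["Rscript", "-e", rcode],
                             capture_output=True, text=True, timeout=120)
        if out.returncode != 0:
            pytest.skip(f"glmnet unavailable: {out.stderr[-200:]}")
        ref = np.array([float(v) for v in out.stdout.strip().split(",")])
        ref = ref.reshape(7, 3, order="F")  # rows: intercept + 6 coefs
        for k, lam in enumerate((0.3, 0.15, 0.05)):
            res = fit_lasso(X, y, lam)
            assert np.allclose(res.coefficients, ref[1:, k], atol=1e-5)
            assert res.intercept == pytest.approx(ref[0, k], abs=1e-5)


# ---------------------------------------------------------------------------
# elastic net
# ---------------------------------------------------------------------------

class TestElasticNet:
    def test_alpha_zero_is_lasso(self, small_regression):
        X, y, _ = small_regression
        a = fit_elastic_net(X, y, 0.1, alpha=0.0)
        b = fit_lasso(X, y, 0.1)
        assert np.allclose(a.coefficients, b.coefficients, atol=1e-10)

    def test_alpha_one_is_ridge_closed_form(self, small_regression):
        X, y, _ = small_regression
        lam = 0.2
        res = fit_elastic_net(X, y, lam, alpha=1.0)
        Xs, ys, xm, xsd, ym = standardize(X, y)
        G, c = gram(Xs, ys)
        beta_std = np.linalg.solve(G + 2 * lam * np.eye(G.shape[0]), c)
        assert np.allclose(res.coefficients, beta_std / xsd, atol=1e-8)

    def test_augmented_design_reduction(self):
        """Naive elastic net == lasso on the augmented design, 20 instances.

        With RSS-scale penalties l1, l2: augment X* = [X; sqrt(l2) I] /
        sqrt(1+l2), y* = [y; 0]; the lasso solution at l1/sqrt(1+l2),
        divided by sqrt(1+l2), is the elastic-net solution.
        """
        for X, y, _ in random_instances(20, seed=99):
            n, p = X.shape
            Xs, ys, *_ = standardize(X, y)
            l1, l2 = 0.8, 0.6  # RSS-scale penalties
            G, c = gram(Xs, ys)
            direct = np.zeros(p)
            _cd_gram(G, c, direct, l1 / (2 * n), l2 / (2 * n), np.ones(p),
                     1e-12, 100_000)
            s = np.sqrt(1 + l2)
            Xa = np.vstack([Xs, np.sqrt(l2) * np.eye(p)]) / s
            ya = np.concatenate([ys, np.zeros(p)])
            na = n + p
            Ga, ca = Xa.T @ Xa / na, Xa.T @ ya / na
            aug = np.zeros(p)
            _cd_gram(Ga, ca, aug, (l1 / s) / (2 * na), 0.0, np.ones(p),
                     1e-12, 100_000)
            assert np.allclose(direct, aug / s, atol=1e-8)

    def test_alpha_out_of_range(self, small_regression):
        X, y, _ = small_regression
        with pytest.raises(ValueError):
            fit_elastic_net(X, y, 0.1, alpha=1.5)


# ---------------------------------------------------------------------------
# adaptive lasso
# ---------------------------------------------------------------------------

class TestAdaptiveLasso:
    def test_unit_weights_reduce_to_lasso(self, small_regression):
        X, y, _ = small_regression
        a = fit_adaptive_lasso(X, y, 0.1, weights=np.ones(X.shape[1]))
        b = fit_lasso(X, y, 0.1)
        assert np.allclose(a.coefficients, b.coefficients, atol=1e-10)

    def test_orthonormal_per_coordinate_thresholds(self, rng):
        X = _orthonormalize(rng.standard_normal((60, 4)))
        beta = np.array([2.0, -1.5, 0.0, 0.4])
        y = X @ beta + 0.2 * rng.standard_normal(60)
        w = np.array([0.5, 1.0, 4.0, 2.0])
        lam = 0.3
        res = fit_adaptive_lasso(X, y, lam, weights=w)
        ols = _ols(X, y)
        assert np.allclose(res.coefficients, soft_threshold(ols, lam * w),
                           atol=1e-8)

    def test_weighted_lambda_max_zeroes_everything(self, small_regression):
        X, y, _ = small_regression
        Xs, ys, *_ = standardize(X, y)
        n = len(ys)
        from penbench.solvers import adaptive_weights, initial_estimate
        G, c = gram(Xs, ys)
        w = adaptive_weights(initial_estimate(G, c, n), 1.0)
        lam_max_w = np.max(np.abs(Xs.T @ ys) / (n * w))
        res = fit_adaptive_lasso(X, y, lam_max_w * 1.000001)
        assert np.all(res.coefficients == 0)


# ---------------------------------------------------------------------------
# SCAD
# ---------------------------------------------------------------------------

def _scad_objective(G, c, beta, lam, a):
    return 0.5 * beta @ G @ beta - c @ beta + scad_penalty(
        np.abs(beta), lam, a).sum()


class TestScad:
    def test_lambda_zero_is_ols(self, small_regression):
        X, y, _ = small_regression
        res = fit_scad(X, y, 0.0)
        assert np.allclose(res.coefficients, _ols(X, y), atol=1e-6)

    def test_one_dimensional_grid_oracle(self):
        """LQA solution matches brute-force minimization of the objective."""
        rng = np.random.default_rng(42)
        grid = np.arange(-10, 10, 1e-4)
        for lam in (0.1, 0.5, 1.5):
            for _ in range(5):
                n = 30
                x = rng.standard_normal(n)
                y = rng.uniform(-3, 3) * x + rng.standard_normal(n)
                res = fit_scad(x[:, None], y, lam)
                xs, ys, xm, xsd, ym = standardize(x[:, None], y)
                G, cvec = gram(xs, ys)
                obj = (0.5 * G[0, 0] * grid**2 - cvec[0] * grid
                       + scad_penalty(np.abs(grid), lam, 3.7))
                best = grid[np.argmin(obj)]
                assert res.coefficients[0] * xsd[0] == pytest.approx(
                    best, abs=1e-3)

    def test_near_unbiasedness_of_large_coefficients(self, rng):
        # |beta_j| >> a*lambda: the flat penalty region leaves the OLS
        # estimate essentially untouched
        n, p = 500, 3
        X = rng.standard_normal((n, p))
        beta = np.array([5.0, 4.0, 3.0])
        y = X @ beta + rng.standard_normal(n)
        lam = 0.2  # a*lam = 0.74 << min|beta|
        res = fit_scad(X, y, lam)
        ols = _ols(X, y)
        sigma2 = np.sum((y - y.mean() - (X - X.mean(0)) @ ols) ** 2) / (n - p - 1)
        se = np.sqrt(sigma2 * np.diag(np.linalg.inv(X.T @ X)))
        assert np.all(np.abs(res.coefficients - ols) < 2 * se)

    def test_all_zero_stationary_at_large_lambda(self, small_regression):
        X, y, _ = small_regression
        res = fit_scad(X, y, 50.0)
        assert np.all(res.coefficients == 0)

    def test_invalid_a(self, small_regression):
        X, y, _ = small_regression
        with pytest.raises(ValueError):
            fit_scad(X, y, 0.1, a=2.0)

    def test_lqa_objective_monotone(self, small_regression):
        """The SCAD objective is non-increasing across LQA iterations."""
        X, y, _ = small_regression
        Xs, ys, *_ = standardize(X, y)
        G, c = gram(Xs, ys)
        from penbench.solvers import initial_estimate
        init = initial_estimate(G, c, len(ys))
        lam, a = 0.3, 3.7
        objs = []
        for k in range(1, 12):
            beta, _, _ = _lqa_scad(G, c, lam, a, init, 0.0, k, LQA_DROP_TOL)
            objs.append(_scad_objective(G, c, beta, lam, a))
        assert all(b <= a_ + 1e-10 for a_, b in zip(objs, objs[1:]))


# ---------------------------------------------------------------------------
# cross-cutting invariants
# ---------------------------------------------------------------------------

class TestKKT:
    def test_kkt_residual_small_on_random_instances(self):
        rng = np.random.default_rng(5)
        for X, y, _ in random_instances(20, seed=7):
            Xs, ys, *_ = standardize(X, y)
            lam_max = np.abs(Xs.T @ ys).max() / len(ys)
            lam = float(rng.uniform(0.05, 0.9) * lam_max)
            for spec, res in [
                (PenaltySpec("lasso", lam), fit_lasso(X, y, lam)),
                (PenaltySpec("elastic_net", lam, alpha=0.4),
                 fit_elastic_net(X, y, lam, 0.4)),
                (PenaltySpec("adaptive_lasso", lam),
                 fit_adaptive_lasso(X, y, lam)),
            ]:
                assert res.converged
                assert kkt_residual(X, y, res, spec) <= 1e-6

    def test_cd_objective_monotone_across_sweeps(self, small_regression):
        X, y, _ = small_regression
        Xs, ys, *_ = standardize(X, y)
        G, c = gram(Xs, ys)
        p = G.shape[0]
        lam = 0.05
        objs = []
        for k in range(1, 10):
            beta = np.zeros(p)
            _cd_gram(G, c, beta, lam, 0.0, np.ones(p), 0.0, k)
            objs.append(0.5 * beta @ G @ beta - c @ beta
                        + lam * np.abs(beta).sum())
        assert all(b <= a + 1e-12 for a, b in zip(objs, objs[1:]))
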