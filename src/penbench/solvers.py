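"""Penalized least-squares solvers: Lasso, Elastic-Net, Adaptive Lasso, SCAD.

All four estimators minimize

    (1 / 2n) * ||y - b0 - X b||^2  +  P_lambda(b)

with penalties

    lasso          P = lambda * sum_j |b_j|
    elastic net    P = lambda * [(1 - alpha) * sum|b_j| + alpha * sum b_j^2]
    adaptive lasso P = lambda * sum_j w_j |b_j|,  w_j = 1 / |b_init_j|^gamma
    scad           P = sum_j scad_penalty(|b_j|; lambda, a)

The convex penalties share one cyclic coordinate-descent core operating on
the Gram matrix G = X'X/n and correlation vector c = X'y/n of internally
standardized data (columns centered and scaled to unit variance, response
centered); SCAD is solved by iterating a local quadratic approximation (LQA)
of its penalty, each step a generalized ridge solve on the active set.
Coefficients are always reported back-transformed to the original predictor
scale with the intercept recovered.

Note the 1/2n loss scaling: a penalty level quoted for the unscaled residual
sum of squares maps to lambda_here = lambda_rss / (2n).
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit

__all__ = [
    "PenaltySpec",
    "FitResult",
    "soft_threshold",
    "scad_penalty",
    "scad_penalty_derivative",
    "adaptive_weights",
    "fit_lasso",
    "fit_elastic_net",
    "fit_adaptive_lasso",
    "fit_scad",
    "fit",
    "kkt_residual",
    "METHODS",
]

METHODS = ("lasso", "elastic_net", "adaptive_lasso", "scad")

# Solver tolerances: convergence is declared when the maximum coefficient
# update, relative to the largest coefficient magnitude, falls below TOL.
TOL = 1e-6
MAX_SWEEPS = 10_000
LQA_MAX_ITER = 500
LQA_DROP_TOL = 1e-6
WEIGHT_CAP = 1e8
RIDGE_INIT_PENALTY = 1e-3  # ridge penalty for initial estimates when n <= p


# ---------------------------------------------------------------------------
# penalty primitives
# ---------------------------------------------------------------------------

def soft_threshold(z, t):
    """sign(z) * max(|z| - t, 0), elementwise."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("threshold t must be nonnegative")
    z = np.asarray(z, dtype=float)
    out = np.sign(z) * np.maximum(np.abs(z) - t, 0.0)
    return out if out.ndim else float(out)


def scad_penalty(beta_abs, lam: float, a: float):
    """Three-branch SCAD penalty evaluated at |beta|.

    lambda*|b| up to lambda, a smoothly clipped quadratic between lambda and
    a*lambda, and the constant (a+1)*lambda^2/2 beyond a*lambda.
    """
    if a <= 2:
        raise ValueError(f"SCAD a must be > 2, got {a}")
    if lam < 0:
        raise ValueError("lambda must be nonnegative")
    b = np.abs(np.asarray(beta_abs, dtype=float))
    out = np.where(
        b <= lam,
        lam * b,
        np.where(
            b < a * lam,
            (2 * a * lam * b - b**2 - lam**2) / (2 * (a - 1)),
            (a + 1) * lam**2 / 2,
        ),
    )
    return out if out.ndim else float(out)


def scad_penalty_derivative(beta, lam: float, a: float):
    """d/d(beta) of the SCAD penalty; continuous, zero beyond a*lambda."""
    if a <= 2:
        raise ValueError(f"SCAD a must be > 2, got {a}")
    b = np.asarray(beta, dtype=float)
    ab = np.abs(b)
    mag = np.where(
        ab <= lam,
        lam,
        np.where(ab < a * lam, (a * lam - ab) / (a - 1), 0.0),
    )
    out = np.sign(b) * mag
    return out if out.ndim else float(out)


def adaptive_weights(beta_init, gamma: float = 1.0) -> np.ndarray:
    """Adaptive-lasso weights w_j = 1/|beta_init_j|^gamma, capped at 1e8.

    A zero initial estimate would give an infinite weight; the cap keeps the
    weight finite while still effectively excluding the coordinate.
    """
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    b = np.abs(np.asarray(beta_init, dtype=float))
    with np.errstate(divide="ignore", over="ignore"):
        w = np.where(b > 0, b**-gamma, np.inf)
    return np.minimum(w, WEIGHT_CAP)


# ---------------------------------------------------------------------------
# result / spec containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PenaltySpec:
    """Method identifier plus its hyperparameters."""

    method: str
    lam: float = 0.0
    alpha: float = 0.5
    scad_a: float = 3.7
    gamma: float = 1.0
    weights: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}; expected one of {METHODS}")
        if self.lam < 0:
            raise ValueError("lambda must be nonnegative")
        if not (0.0 <= self.alpha <= 1.0):
            raise ValueError("alpha must be in [0, 1]")
        if self.scad_a <= 2:
            raise ValueError("SCAD a must be > 2")
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")
        if self.weights is not None and any(w <= 0 for w in self.weights):
            raise ValueError("weights must be positive")

    def with_lambda(self, lam: float) -> "PenaltySpec":
        return PenaltySpec(self.method, lam, self.alpha, self.scad_a,
                           self.gamma, self.weights)


@dataclass
class FitResult:
    """A fitted penalized regression on the original predictor scale."""

    coefficients: np.ndarray
    intercept: float
    n_iterations: int
    converged: bool
    fit_seconds: float
    method: str = ""

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.intercept + np.asarray(X, dtype=float) @ self.coefficients

    def to_frame(self, names: list[str] | None = None) -> pd.DataFrame:
        """Coefficient table (name, estimate), intercept first."""
        p = len(self.coefficients)
        if names is None:
            names = [f"x{j + 1}" for j in range(p)]
        return pd.DataFrame(
            {"name": ["intercept"] + list(names),
             "estimate": np.concatenate([[self.intercept], self.coefficients])}
        )


# ---------------------------------------------------------------------------
# standardization
# ---------------------------------------------------------------------------

def standardize(X: np.ndarray, y: np.ndarray):
    """Center/scale X to unit variance and center y.

    Returns (Xs, ys, x_mean, x_scale, y_mean). Constant columns get scale 1
    (they then carry zero signal and a zero coefficient).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or y.ndim != 1 or X.shape[0] != y.shape[0]:
        raise ValueError("X must be n x p and y length n")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise ValueError("inputs contain non-finite values")
    x_mean = X.mean(axis=0)
    x_scale = X.std(axis=0)
    x_scale[x_scale == 0] = 1.0
    y_mean = y.mean()
    return (X - x_mean) / x_scale, y - y_mean, x_mean, x_scale, y_mean


def _unstandardize(beta_std, x_mean, x_scale, y_mean):
    coef = beta_std / x_scale
    return coef, float(y_mean - coef @ x_mean)


def gram(Xs: np.ndarray, ys: np.ndarray):
    """G = X'X/n and c = X'y/n of standardized data."""
    n = Xs.shape[0]
    return Xs.T @ Xs / n, Xs.T @ ys / n


# ---------------------------------------------------------------------------
# coordinate-descent core (Gram form, numba-compiled)
# ---------------------------------------------------------------------------

@njit(cache=False)
def _cd_gram(G, c, beta, l1, l2, w, tol, max_sweeps):
    """Cyclic coordinate descent on (1/2) b'Gb - c'b + sum l1*w_j|b_j| + l2 b_j^2.

    Updates ``beta`` in place; returns (sweeps, converged). Deterministic
    cyclic order 0..p-1.
    """
    p = G.shape[0]
    grad = c - G @ beta  # c_j - sum_k G_jk beta_k
    for sweep in range(max_sweeps):
        max_delta = 0.0
        max_beta = 1.0
        for j in range(p):
            gjj = G[j, j]
            denom = gjj + 2.0 * l2
            if denom <= 0.0:
                continue
            r = grad[j] + gjj * beta[j]  # partial residual correlation
            t = l1 * w[j]
            if r > t:
                bj = (r - t) / denom
            elif r < -t:
                bj = (r + t) / denom
            else:
                bj = 0.0
            d = bj - beta[j]
            if d != 0.0:
                grad -= G[j] * d  # G symmetric; row j is the contiguous view
                beta[j] = bj
                ad = abs(d)
                if ad > max_delta:
                    max_delta = ad
            ab = abs(bj)
            if ab > max_beta:
                max_beta = ab
        if max_delta / max_beta <= tol:
            return sweep + 1, True
    return max_sweeps, False


@njit(cache=False)
def _cd_gram_path(G, c, lambdas, l1_frac, l2_frac, w, tol, max_sweeps):
    """Warm-started coordinate-descent solutions along a decreasing lambda path.

    Returns (coefs[p, n_lambda], sweeps[n_lambda], converged[n_lambda]).
    """
    p = G.shape[0]
    nl = lambdas.shape[0]
    coefs = np.zeros((p, nl))
    sweeps = np.zeros(nl, dtype=np.int64)
    conv = np.zeros(nl, dtype=np.bool_)
    beta = np.zeros(p)
    for i in range(nl):
        lam = lambdas[i]
        s, ok = _cd_gram(G, c, beta, lam * l1_frac, lam * l2_frac, w,
                         tol, max_sweeps)
        coefs[:, i] = beta
        sweeps[i] = s
        conv[i] = ok
    return coefs, sweeps, conv


# ---------------------------------------------------------------------------
# SCAD via local quadratic approximation (LQA)
# ---------------------------------------------------------------------------

@njit(cache=False)
def _lqa_scad(G, c, lam, a, beta_init, tol, max_iter, drop_tol):
    """LQA iteration for the SCAD-penalized problem on the Gram system.

    At iterate b, each penalty term is majorized by a quadratic with
    curvature P'(|b_j|)/|b_j|; the resulting generalized ridge system is
    solved on the current active set, coordinates falling below ``drop_tol``
    are zeroed and dropped, and the process repeats to convergence.
    Returns (beta, iterations, converged).
    """
    p = G.shape[0]
    beta = np.zeros(p)
    # all-zero is a stationary point iff every |c_j| <= P'(0+) = lambda
    if lam > 0.0:
        all_small = True
        for j in range(p):
            if abs(c[j]) > lam:
                all_small = False
                break
        if all_small:
            return beta, 0, True
    active = np.zeros(p, dtype=np.bool_)
    for j in range(p):
        beta[j] = beta_init[j]
        active[j] = abs(beta_init[j]) > drop_tol
    for it in range(max_iter):
        na = 0
        for j in range(p):
            if active[j]:
                na += 1
        idx = np.empty(na, dtype=np.int64)
        k = 0
        for j in range(p):
            if active[j]:
                idx[k] = j
                k += 1
        if na == 0:
            return np.zeros(p), it + 1, True
        A = np.empty((na, na))
        rhs = np.empty(na)
        for ii in range(na):
            j = idx[ii]
            rhs[ii] = c[j]
            for kk in range(na):
                A[ii, kk] = G[j, idx[kk]]
            ab = abs(beta[j])
            # SCAD derivative at |b_j|
            if ab <= lam:
                d1 = lam
            elif ab < a * lam:
                d1 = (a * lam - ab) / (a - 1.0)
            else:
                d1 = 0.0
            A[ii, ii] += d1 / ab
        # ridge-jitter retry ladder for near-singular systems
        sol = np.linalg.solve(A + 1e-12 * np.eye(na), rhs)
        new_beta = np.zeros(p)
        max_delta = 0.0
        max_beta = 1.0
        for ii in range(na):
            j = idx[ii]
            bj = sol[ii]
            if abs(bj) <= drop_tol:
                bj = 0.0
                active[j] = False
            new_beta[j] = bj
            d = abs(bj - beta[j])
            if d > max_delta:
                max_delta = d
            if abs(bj) > max_beta:
                max_beta = abs(bj)
        beta = new_beta
        if max_delta / max_beta <= tol:
            return beta, it + 1, True
    return beta, max_iter, False


def scad_path_gram(G, c, lambdas, a, beta_init,
                   tol=TOL, max_iter=LQA_MAX_ITER, drop_tol=LQA_DROP_TOL):
    """LQA SCAD solutions for each lambda, each started from ``beta_init``."""
    p = G.shape[0]
    nl = len(lambdas)
    coefs = np.zeros((p, nl))
    iters = np.zeros(nl, dtype=int)
    conv = np.zeros(nl, dtype=bool)
    for i, lam in enumerate(lambdas):
        coefs[:, i], iters[i], conv[i] = _lqa_scad(
            G, c, lam, a, beta_init, tol, max_iter, drop_tol)
    return coefs, iters, conv


# ---------------------------------------------------------------------------
# initial estimates (adaptive lasso weights, SCAD LQA start)
# ---------------------------------------------------------------------------

def initial_estimate(G: np.ndarray, c: np.ndarray, n: int) -> np.ndarray:
    """OLS when n > p, else a lightly ridge-penalized estimate.

    Computed on the standardized scale; serves as the sqrt(n)-consistent
    initializer for adaptive-lasso weights and the SCAD LQA start.
    """
    p = G.shape[0]
    if n > p:
        try:
            return np.linalg.solve(G, c)
        except np.linalg.LinAlgError:
            pass
    return np.linalg.solve(G + 2 * RIDGE_INIT_PENALTY * np.eye(p), c)


# ---------------------------------------------------------------------------
# public fit functions
# ---------------------------------------------------------------------------

def _finalize(beta_std, iters, conv, x_mean, x_scale, y_mean, t0, method):
    coef, intercept = _unstandardize(beta_std, x_mean, x_scale, y_mean)
    return FitResult(coef, intercept, int(iters), bool(conv),
                     time.perf_counter() - t0, method)


def _fit_enet_like(X, y, lam, l1_frac, l2_frac, weights, method,
                   tol=TOL, max_sweeps=MAX_SWEEPS):
    t0 = time.perf_counter()
    Xs, ys, xm, xsd, ym = standardize(X, y)
    G, c = gram(Xs, ys)
    p = G.shape[0]
    w = np.ones(p) if weights is None else np.asarray(weights, dtype=float)
    beta = np.zeros(p)
    sweeps, conv = _cd_gram(G, c, beta, lam * l1_frac, lam * l2_frac, w,
                            tol, max_sweeps)
    return _finalize(beta, sweeps, conv, xm, xsd, ym, t0, method)


def fit_lasso(X, y, lam: float, tol: float = TOL,
              max_sweeps: int = MAX_SWEEPS) -> FitResult:
    """L1-penalized least squares by cyclic coordinate descent."""
    if lam < 0:
        raise ValueError("lambda must be nonnegative")
    return _fit_enet_like(X, y, lam, 1.0, 0.0, None, "lasso", tol, max_sweeps)


def fit_elastic_net(X, y, lam: float, alpha: float = 0.5, tol: float = TOL,
                    max_sweeps: int = MAX_SWEEPS) -> FitResult:
    """Elastic net: penalty lambda*[(1-alpha)*l1 + alpha*l2^2].

    alpha = 0 reduces to the lasso, alpha = 1 to ridge regression.
    """
    if lam < 0:
        raise ValueError("lambda must be nonnegative")
    if not (0.0 <= alpha <= 1.0):
        raise ValueError("alpha must be in [0, 1]")
    return _fit_enet_like(X, y, lam, 1.0 - alpha, alpha, None, "elastic_net",
                          tol, max_sweeps)


def fit_adaptive_lasso(X, y, lam: float, gamma: float = 1.0,
                       weights=None, tol: float = TOL,
                       max_sweeps: int = MAX_SWEEPS) -> FitResult:
    """Weighted-L1 lasso with data-driven weights 1/|beta_init|^gamma.

    The initial estimate is OLS when n > p and a small-ridge fit otherwise;
    explicit ``weights`` (on the standardized scale) override it.
    """
    if lam < 0:
        raise ValueError("lambda must be nonnegative")
    t0 = time.perf_counter()
    Xs, ys, xm, xsd, ym = standardize(X, y)
    G, c = gram(Xs, ys)
    if weights is None:
        weights = adaptive_weights(initial_estimate(G, c, Xs.shape[0]), gamma)
    w = np.asarray(weights, dtype=float)
    beta = np.zeros(G.shape[0])
    sweeps, conv = _cd_gram(G, c, beta, lam, 0.0, w, tol, max_sweeps)
    return _finalize(beta, sweeps, conv, xm, xsd, ym, t0, "adaptive_lasso")


def fit_scad(X, y, lam: float, a: float = 3.7, tol: float = TOL,
             max_iter: int = LQA_MAX_ITER) -> FitResult:
    """SCAD-penalized least squares by local quadratic approximation.

    Converges to a stationary point (a local optimum of the non-convex
    objective), started from the OLS/ridge initial estimate.
    """
    if lam < 0:
        raise ValueError("lambda must be nonnegative")
    if a <= 2:
        raise ValueError("SCAD a must be > 2")
    t0 = time.perf_counter()
    Xs, ys, xm, xsd, ym = standardize(X, y)
    G, c = gram(Xs, ys)
    init = initial_estimate(G, c, Xs.shape[0])
    beta, iters, conv = _lqa_scad(G, c, lam, a, init, tol, max_iter,
                                  LQA_DROP_TOL)
    return _finalize(beta, iters, conv, xm, xsd, ym, t0, "scad")


_FITTERS = {
    "lasso": lambda X, y, s: fit_lasso(X, y, s.lam),
    "elastic_net": lambda X, y, s: fit_elastic_net(X, y, s.lam, s.alpha),
    "adaptive_lasso": lambda X, y, s: fit_adaptive_lasso(
        X, y, s.lam, s.gamma, s.weights),
    "scad": lambda X, y, s: fit_scad(X, y, s.lam, s.scad_a),
}


def fit(X, y, spec: PenaltySpec) -> FitResult:
    """Single entry point keyed by PenaltySpec."""
    return _FITTERS[spec.method](X, y, spec)


# ---------------------------------------------------------------------------
# diagnostics
# ---------------------------------------------------------------------------

def kkt_residual(X, y, result: FitResult, spec: PenaltySpec) -> float:
    """Max violation of the stationarity conditions on the standardized scale.

    Applies to the convex penalties (lasso / elastic net / adaptive lasso).
    """
    if spec.method == "scad":
        raise ValueError("KKT residual is defined here for convex penalties only")
    Xs, ys, xm, xsd, ym = standardize(X, y)
    G, c = gram(Xs, ys)
    beta_std = result.coefficients * xsd
    if spec.method == "lasso":
        l1, l2 = spec.lam, 0.0
        w = np.ones_like(beta_std)
    elif spec.method == "elastic_net":
        l1, l2 = spec.lam * (1 - spec.alpha), spec.lam * spec.alpha
        w = np.ones_like(beta_std)
    else:
        l1, l2 = spec.lam, 0.0
        if spec.weights is not None:
            w = np.asarray(spec.weights, dtype=float)
        else:
            w = adaptive_weights(initial_estimate(G, c, Xs.shape[0]), spec.gamma)
    g = c - G @ beta_std - 2 * l2 * beta_std
    viol = np.where(
        beta_std != 0,
        np.abs(g - l1 * w * np.sign(beta_std)),
        np.maximum(np.abs(g) - l1 * w, 0.0),
    )
    return float(viol.max())
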