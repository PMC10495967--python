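"""Penalty-level selection: lambda paths, K-fold CV and GCV.

The lambda grid is log-spaced from lambda_max — the smallest penalty at
which every slope is exactly zero, max_j |x_j'y|/n on standardized data —
down to lambda_max * min_ratio.  The default minimum ratio is 0.001 in the
classical n > p regime and 0.05 in the high-dimensional n <= p regime,
where very small penalties interpolate the data.

Ten-fold cross-validation with the minimum-mean-MSE rule is the primary
selector (no one-standard-error rule); generalized cross-validation with
degrees of freedom equal to the active-set size (+1 for the intercept) is
provided as a cheaper alternative.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold

from .solvers import (
    PenaltySpec,
    _cd_gram_path,
    adaptive_weights,
    fit,
    gram,
    initial_estimate,
    scad_path_gram,
    standardize,
)

__all__ = [
    "LambdaPath",
    "TuningResult",
    "lambda_path",
    "cross_validate",
    "gcv_score",
    "gcv_select",
]

DEFAULT_N_VALUES = 50
DEFAULT_FOLDS = 10


@dataclass(frozen=True)
class LambdaPath:
    values: np.ndarray
    lambda_max: float
    min_ratio: float

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if len(v) < 1 or np.any(v <= 0) or np.any(np.diff(v) >= 0):
            raise ValueError("path values must be positive and strictly decreasing")
        object.__setattr__(self, "values", v)


@dataclass
class TuningResult:
    best_lambda: float
    lambdas: np.ndarray
    cv_mse_by_lambda: np.ndarray
    se_by_lambda: np.ndarray
    folds: int

    def to_frame(self) -> pd.DataFrame:
        """Diagnostics table (lambda, cv_mse, cv_se) for CV-curve plots."""
        return pd.DataFrame({
            "lambda": self.lambdas,
            "cv_mse": self.cv_mse_by_lambda,
            "cv_se": self.se_by_lambda,
        })


def lambda_path(X, y, n_values: int = DEFAULT_N_VALUES,
                min_ratio: float | None = None) -> LambdaPath:
    """Log-spaced lambda grid from lambda_max down to lambda_max*min_ratio."""
    if n_values < 2:
        raise ValueError("n_values must be >= 2")
    Xs, ys, *_ = standardize(X, y)
    n, p = Xs.shape
    lam_max = float(np.abs(Xs.T @ ys).max() / n)
    if lam_max <= 0:
        raise ValueError("degenerate input: response is constant")
    if min_ratio is None:
        min_ratio = 0.001 if n > p else 0.05
    if not (0 < min_ratio < 1):
        raise ValueError("min_ratio must be in (0, 1)")
    values = np.geomspace(lam_max, lam_max * min_ratio, n_values)
    return LambdaPath(values, lam_max, min_ratio)


def path_coefficients(G: np.ndarray, c: np.ndarray, n: int,
                      spec: PenaltySpec, lambdas: np.ndarray):
    """Standardized-scale solutions at every lambda (p x n_lambda).

    Convex penalties are solved warm-started down the path; SCAD restarts
    the LQA from its OLS/ridge initializer at each lambda.
    """
    from .solvers import MAX_SWEEPS, TOL

    p = G.shape[0]
    if spec.method == "scad":
        init = initial_estimate(G, c, n)
        coefs, _, conv = scad_path_gram(G, c, lambdas, spec.scad_a, init)
        return coefs, conv
    if spec.method == "lasso":
        l1f, l2f, w = 1.0, 0.0, np.ones(p)
    elif spec.method == "elastic_net":
        l1f, l2f, w = 1.0 - spec.alpha, spec.alpha, np.ones(p)
    else:  # adaptive_lasso
        l1f, l2f = 1.0, 0.0
        if spec.weights is not None:
            w = np.asarray(spec.weights, dtype=float)
        else:
            w = adaptive_weights(initial_estimate(G, c, n), spec.gamma)
    coefs, _, conv = _cd_gram_path(G, c, np.asarray(lambdas, dtype=float),
                                   l1f, l2f, w, TOL, MAX_SWEEPS)
    return coefs, conv


def fold_assignments(n: int, folds: int, seed: int) -> list[np.ndarray]:
    """Seeded, shuffled K-fold test-index sets, shared across methods."""
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    return [test_idx for _, test_idx in kf.split(np.arange(n))]


def cross_validate(X, y, spec: PenaltySpec, path: LambdaPath,
                   folds: int = DEFAULT_FOLDS, seed: int = 0,
                   fold_indices: list[np.ndarray] | None = None) -> TuningResult:
    """K-fold CV over the path; returns the minimum-mean-MSE lambda.

    ``fold_indices`` allows several methods to share one seeded fold
    assignment so comparisons are paired.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if folds < 2:
        raise ValueError("folds must be >= 2")
    if n < folds:
        raise ValueError("need at least one row per fold")
    if fold_indices is None:
        fold_indices = fold_assignments(n, folds, seed)
    lambdas = path.values
    fold_mse = np.empty((len(fold_indices), len(lambdas)))
    mask = np.ones(n, dtype=bool)
    for f, test_idx in enumerate(fold_indices):
        mask[:] = True
        mask[test_idx] = False
        if mask.sum() < 2:
            raise ValueError("fold with fewer than 2 training rows")
        Xs, ys, xm, xsd, ym = standardize(X[mask], y[mask])
        G, c = gram(Xs, ys)
        coefs, _ = path_coefficients(G, c, Xs.shape[0], spec, lambdas)
        preds = ym + ((X[test_idx] - xm) / xsd) @ coefs
        fold_mse[f] = ((preds - y[test_idx][:, None]) ** 2).mean(axis=0)
    cv_mse = fold_mse.mean(axis=0)
    cv_se = fold_mse.std(axis=0, ddof=1) / np.sqrt(len(fold_indices))
    best = float(lambdas[int(np.argmin(cv_mse))])
    return TuningResult(best, lambdas.copy(), cv_mse, cv_se, len(fold_indices))


def gcv_score(X, y, spec: PenaltySpec, lam: float) -> float:
    """Generalized cross-validation: RSS / (n * (1 - df/n)^2).

    df counts the nonzero coefficients plus one for the intercept.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    res = fit(X, y, spec.with_lambda(lam))
    df = int(np.count_nonzero(res.coefficients)) + 1
    if df >= n:
        raise ValueError("GCV undefined: degrees of freedom >= n")
    rss = float(((y - res.predict(X)) ** 2).sum())
    return rss / (n * (1.0 - df / n) ** 2)


def gcv_select(X, y, spec: PenaltySpec, path: LambdaPath) -> tuple[float, np.ndarray]:
    """Lambda on the path minimizing GCV, plus the score curve."""
    scores = np.array([gcv_score(X, y, spec, lam) for lam in path.values])
    return float(path.values[int(np.argmin(scores))]), scores
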