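"""Model-quality metrics for the variable-selection benchmark.

Four indicators per fitted model:

* **Angle** — (180/pi) * arccos of the inner product of the unit-normalized
  true and estimated coefficient vectors; 0 deg means perfect directional
  agreement, 90 deg orthogonality.  Undefined (reported missing) when the
  estimate is the zero vector.
* **Err** — test-set mean squared prediction error, bounded below in
  expectation by the irreducible noise variance.
* **VC / VD** — counts of correctly retained nonzero coefficients and
  correctly eliminated zero coefficients; summarized as selection and
  rejection rates.
* **Outlier counts** — Tukey boxplot outliers of Angle and Err across
  replicates, a stability indicator.

Summaries use medians for Angle and Err (robust to the occasional wild
replicate) and means for the counting metrics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

__all__ = [
    "MetricRecord",
    "SummaryRow",
    "angle_statistic",
    "test_mse",
    "selection_counts",
    "coefficient_error",
    "tukey_outlier_count",
    "summarize",
]

ZERO_TOL = 1e-8  # a coefficient below this magnitude counts as eliminated

SUMMARY_COLUMNS = [
    "method", "cor", "angle_median", "angle_outliers", "err_median",
    "err_outliers", "selection_rate", "rejection_rate", "coef_error_mean",
    "time_mean_seconds", "n_replicates", "n_angle_missing",
]

RECORD_COLUMNS = [
    "method", "cor", "replicate", "angle_deg", "err", "vc", "vd",
    "coef_error", "fit_seconds",
]


@dataclass
class MetricRecord:
    """Per-replicate evaluation of one method."""

    method: str
    cor: float
    replicate: int
    angle_deg: float  # NaN when the estimate was the zero vector
    err: float
    vc: int
    vd: int
    coef_error: float
    fit_seconds: float

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SummaryRow:
    """Aggregate over the replicates of one (method, cor) cell."""

    method: str
    cor: float
    angle_median: float
    angle_outliers: int | None
    err_median: float
    err_outliers: int | None
    selection_rate: float
    rejection_rate: float
    coef_error_mean: float
    time_mean_seconds: float
    n_replicates: int
    n_angle_missing: int

    def to_dict(self) -> dict:
        return asdict(self)


def angle_statistic(beta_true, beta_hat) -> float:
    """Angle in degrees between the unit-normalized coefficient vectors.

    Returns NaN for a zero estimate (the direction is undefined); the inner
    product is clamped to [-1, 1] before arccos to absorb rounding.
    """
    bt = np.asarray(beta_true, dtype=float)
    bh = np.asarray(beta_hat, dtype=float)
    if bt.shape != bh.shape:
        raise ValueError("coefficient vectors must have equal length")
    nt = np.linalg.norm(bt)
    if nt == 0:
        raise ValueError("beta_true must not be the zero vector")
    nh = np.linalg.norm(bh)
    if nh == 0:
        return math.nan
    cosang = float(np.clip(bt @ bh / (nt * nh), -1.0, 1.0))
    return math.degrees(math.acos(cosang))


def test_mse(y_pred, y_true) -> float:
    """Mean squared prediction error (1/n) * sum (yhat - y)^2."""
    yp = np.asarray(y_pred, dtype=float)
    yt = np.asarray(y_true, dtype=float)
    if yp.shape != yt.shape or yp.size == 0:
        raise ValueError("predictions and truth must be equal-length, nonempty")
    return float(np.mean((yp - yt) ** 2))


test_mse.__test__ = False  # library function, not a pytest case


def selection_counts(beta_true, beta_hat, zero_tol: float = ZERO_TOL):
    """(vc, vd): true nonzeros retained and true zeros eliminated."""
    bt = np.asarray(beta_true, dtype=float)
    bh = np.asarray(beta_hat, dtype=float)
    if bt.shape != bh.shape:
        raise ValueError("coefficient vectors must have equal length")
    active = bt != 0
    vc = int(np.sum(np.abs(bh[active]) > zero_tol))
    vd = int(np.sum(np.abs(bh[~active]) <= zero_tol))
    return vc, vd


def coefficient_error(beta_true, beta_hat, kind: str = "mad") -> float:
    """Coefficient estimation error; mean absolute deviation by default.

    ``kind`` may be "mad" ((1/p) sum |bh - bt|), "rmse" or "l2".
    """
    bt = np.asarray(beta_true, dtype=float)
    bh = np.asarray(beta_hat, dtype=float)
    if bt.shape != bh.shape:
        raise ValueError("coefficient vectors must have equal length")
    d = bh - bt
    if kind == "mad":
        return float(np.mean(np.abs(d)))
    if kind == "rmse":
        return float(np.sqrt(np.mean(d**2)))
    if kind == "l2":
        return float(np.linalg.norm(d))
    raise ValueError(f"unknown error kind {kind!r}")


def tukey_outlier_count(values) -> int:
    """Points outside the Tukey fences Q1 - 1.5*IQR, Q3 + 1.5*IQR.

    Quartiles by linear interpolation between order statistics (the standard
    boxplot convention). Requires at least 4 finite values.
    """
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size < 4:
        raise ValueError("need at least 4 finite values for an outlier count")
    q1, q3 = np.percentile(v, [25, 75])
    iqr = q3 - q1
    return int(np.sum((v < q1 - 1.5 * iqr) | (v > q3 + 1.5 * iqr)))


def summarize(records: list[MetricRecord], n_signal: int | None = None,
              n_null: int | None = None) -> SummaryRow:
    """Collapse the replicates of one (method, cor) cell into a SummaryRow.

    ``n_signal`` and ``n_null`` are |S0| and p - |S0|; when omitted, the
    maxima of vc and vd over the records are used (exact whenever some
    replicate attains a perfect selection/rejection, otherwise a lower
    bound — pass the sizes explicitly for guaranteed rates).  Missing
    angles (zero
    estimates) are excluded from the angle median and counted separately;
    outlier counts require >= 4 usable values and are reported as missing
    (None) below that.
    """
    if not records:
        raise ValueError("cannot summarize an empty cell")
    methods = {r.method for r in records}
    cors = {r.cor for r in records}
    if len(methods) != 1 or len(cors) != 1:
        raise ValueError("summarize expects records from a single (method, cor) cell")
    angles = np.array([r.angle_deg for r in records], dtype=float)
    errs = np.array([r.err for r in records], dtype=float)
    vcs = np.array([r.vc for r in records], dtype=float)
    vds = np.array([r.vd for r in records], dtype=float)
    ok_angles = angles[np.isfinite(angles)]
    if n_signal is None:
        n_signal = int(vcs.max())
    if n_null is None:
        n_null = int(vds.max())
    if n_signal < 1:
        raise ValueError("could not infer the number of signal coefficients")

    def _outliers(v: np.ndarray) -> int | None:
        return tukey_outlier_count(v) if v.size >= 4 else None

    return SummaryRow(
        method=methods.pop(),
        cor=cors.pop(),
        angle_median=float(np.median(ok_angles)) if ok_angles.size else math.nan,
        angle_outliers=_outliers(ok_angles),
        err_median=float(np.median(errs)),
        err_outliers=_outliers(errs),
        selection_rate=100.0 * float(vcs.mean()) / n_signal,
        rejection_rate=(100.0 * float(vds.mean()) / n_null) if n_null else math.nan,
        coef_error_mean=float(np.mean([r.coef_error for r in records])),
        time_mean_seconds=float(np.mean([r.fit_seconds for r in records])),
        n_replicates=len(records),
        n_angle_missing=int(np.sum(~np.isfinite(angles))),
    )
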