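"""Synthetic data from a sparse linear random-effects model.

Replicate datasets are drawn from

    y = X beta + Z delta + eps,

where the rows of ``X`` are multivariate normal with an equicorrelated
covariance (unit variances, constant pairwise correlation ``cor``) around a
*random* column-mean vector ``mu ~ N(0, I_p)`` redrawn for every replicate.
The random column means are what make the replicates heterogeneous: they
play the role of the random factor ``Z delta`` in the default configuration
(``random_effect_sd = 0``).  An explicit random-effect term with
``Z`` = the first ``q`` columns of ``X`` and ``delta ~ N(0, random_effect_sd^2 I_q)``
is available through the configuration for extensions.

The default coefficient vector has 5 nonzero entries, (1, 1.2, -3.2, 4.1, -5),
followed by zeros, and the noise is standard normal, so the irreducible test
mean-squared error is 1.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SimulationConfig",
    "Dataset",
    "default_beta",
    "equicorrelation_matrix",
    "generate_dataset",
]

#: Signal block of the default sparse coefficient vector.
SIGNAL_BETA = (1.0, 1.2, -3.2, 4.1, -5.0)


def default_beta(p: int) -> np.ndarray:
    """Sparse coefficient vector (1, 1.2, -3.2, 4.1, -5, 0, ..., 0) of length p.

    Parameters
    ----------
    p : int
        Number of predictors; must be at least 5 so the full signal block fits.

    Returns
    -------
    numpy.ndarray
        Length-``p`` vector with 5 nonzero leading entries and ``p - 5`` zeros.
    """
    if p < len(SIGNAL_BETA):
        raise ValueError(f"p must be >= {len(SIGNAL_BETA)}, got {p}")
    beta = np.zeros(p)
    beta[: len(SIGNAL_BETA)] = SIGNAL_BETA
    return beta


def equicorrelation_matrix(p: int, cor: float) -> np.ndarray:
    """Equicorrelation matrix: unit diagonal, constant off-diagonal ``cor``.

    Positive definite for any ``p >= 2`` when ``cor`` is in ``[0, 1)``;
    ``cor = 1`` would be complete collinearity and is rejected.
    """
    if p < 1:
        raise ValueError(f"p must be >= 1, got {p}")
    if not (0.0 <= cor < 1.0):
        raise ValueError(f"cor must be in [0, 1), got {cor}")
    sigma = np.full((p, p), cor)
    np.fill_diagonal(sigma, 1.0)
    return sigma


@dataclass(frozen=True)
class SimulationConfig:
    """Full parameterization of one replicate of the data-generating process.

    Attributes
    ----------
    n_train, n_test : int
        Training / test sample sizes (test defaults to the training size).
    p : int
        Number of predictors.
    cor : float
        Pairwise predictor correlation in [0, 1).
    beta : tuple of float
        True fixed-effect coefficients; defaults to the sparse 5-signal vector.
    noise_sd : float
        Standard deviation of the iid Gaussian noise.
    q : int
        Dimension of the explicit random-effect term (0 disables it; Z is the
        first q columns of X).
    random_effect_sd : float
        Scale of the random-effect coefficients delta.
    seed : int
        Seed of the replicate's random stream.
    """

    n_train: int = 2500
    n_test: int | None = None
    p: int = 50
    cor: float = 0.6
    beta: tuple[float, ...] | None = None
    noise_sd: float = 1.0
    q: int = 0
    random_effect_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_train < 1 or self.p < 1:
            raise ValueError("n_train and p must be positive")
        if self.n_test is not None and self.n_test < 1:
            raise ValueError("n_test must be positive")
        if not (0.0 <= self.cor < 1.0):
            raise ValueError(f"cor must be in [0, 1), got {self.cor}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if not (0 <= self.q <= self.p):
            raise ValueError("q must satisfy 0 <= q <= p")
        if self.random_effect_sd < 0:
            raise ValueError("random_effect_sd must be nonnegative")
        if self.beta is None:
            object.__setattr__(self, "beta", tuple(default_beta(self.p)))
        else:
            object.__setattr__(self, "beta", tuple(float(b) for b in self.beta))
            if len(self.beta) != self.p:
                raise ValueError("beta must have length p")
        if not any(b != 0.0 for b in self.beta):
            raise ValueError("beta must have at least one nonzero entry")

    @property
    def resolved_n_test(self) -> int:
        return self.n_train if self.n_test is None else self.n_test

    @property
    def beta_array(self) -> np.ndarray:
        return np.asarray(self.beta, dtype=float)

    @property
    def active_set(self) -> np.ndarray:
        """Indices of the truly nonzero coefficients (S0)."""
        return np.flatnonzero(self.beta_array)

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if d.get("beta") is not None:
            d["beta"] = tuple(d["beta"])
        return cls(**d)

    @classmethod
    def from_json(cls, path: str | Path) -> "SimulationConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass
class Dataset:
    """One replicate: train/test design matrices, responses and the truth."""

    X_train: np.ndarray
    y_train: np.ndarray
    X_test: np.ndarray
    y_test: np.ndarray
    beta_true: np.ndarray
    mu: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        n_tr, p = self.X_train.shape
        n_te, p2 = self.X_test.shape
        if p != p2 or len(self.y_train) != n_tr or len(self.y_test) != n_te:
            raise ValueError("inconsistent dataset dimensions")
        if len(self.beta_true) != p or len(self.mu) != p:
            raise ValueError("beta_true and mu must have length p")
        for arr in (self.X_train, self.y_train, self.X_test, self.y_test):
            if not np.all(np.isfinite(arr)):
                raise ValueError("dataset contains non-finite values")

    @property
    def p(self) -> int:
        return self.X_train.shape[1]

    def to_csv(self, train_path: str | Path, test_path: str | Path) -> None:
        """Write train and test splits as CSV with columns x1..xp, y."""
        cols = [f"x{j + 1}" for j in range(self.p)]
        for X, y, path in (
            (self.X_train, self.y_train, train_path),
            (self.X_test, self.y_test, test_path),
        ):
            df = pd.DataFrame(X, columns=cols)
            df["y"] = y
            df.to_csv(path, index=False)


def generate_dataset(config: SimulationConfig) -> Dataset:
    """Draw one replicate from the linear random-effects model.

    Column means ``mu_j ~ N(0, 1)`` and (when enabled) random-effect
    coefficients ``delta`` are drawn once per replicate and shared by the
    train and test splits, so both splits come from the same realized
    population. Deterministic given ``config`` (including its seed).
    """
    rng = np.random.default_rng(config.seed)
    p = config.p
    beta = config.beta_array
    sigma = equicorrelation_matrix(p, config.cor)
    chol = np.linalg.cholesky(sigma)

    mu = rng.standard_normal(p)
    delta = (
        config.random_effect_sd * rng.standard_normal(config.q)
        if config.q > 0
        else np.zeros(0)
    )

    def draw(n: int) -> tuple[np.ndarray, np.ndarray]:
        X = mu + rng.standard_normal((n, p)) @ chol.T
        y = X @ beta
        if config.q > 0:
            y = y + X[:, : config.q] @ delta
        y = y + config.noise_sd * rng.standard_normal(n)
        return X, y

    X_train, y_train = draw(config.n_train)
    X_test, y_test = draw(config.resolved_n_test)
    return Dataset(X_train, y_train, X_test, y_test, beta.copy(), mu)
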