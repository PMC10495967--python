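"""End-to-end simulation scenarios and the generic fit-on-CSV command.

Two presets mirror the benchmark's study conditions:

* ``large_sample`` — n_train = 2500, p = 50 (classical n >> p regime);
* ``high_dim``     — n_train = 40,   p = 50 (high-dimensional n < p regime).

Each scenario sweeps a grid of predictor correlations (default
0.2/0.4/0.6/0.8/0.98), runs ``replicates`` independent draws of the
data-generating process per correlation, and for every requested method
tunes lambda by shared-fold 10-fold CV, fits on the training split and
evaluates on the test split.  Within a replicate all methods see identical
data and identical CV fold assignments, so comparisons are paired.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .evaluation import (
    MetricRecord,
    SummaryRow,
    angle_statistic,
    coefficient_error,
    selection_counts,
    summarize,
    test_mse,
)
from .solvers import METHODS, PenaltySpec, fit
from .synthetic import SimulationConfig, generate_dataset
from .tuning import cross_validate, fold_assignments, lambda_path

logger = logging.getLogger("penbench")

__all__ = ["ScenarioSpec", "run_replicate", "run_scenario", "fit_csv"]

DEFAULT_COR_GRID = (0.2, 0.4, 0.6, 0.8, 0.98)

PRESETS = {
    "large_sample": dict(n_train=2500, p=50),
    "high_dim": dict(n_train=40, p=50),
}


@dataclass(frozen=True)
class ScenarioSpec:
    """A full simulation-scenario specification."""

    name: str = "large_sample"
    n_train: int | None = None
    n_test: int | None = None
    p: int | None = None
    cor_grid: tuple[float, ...] = DEFAULT_COR_GRID
    replicates: int = 300
    methods: tuple[str, ...] = METHODS
    master_seed: int = 0
    n_lambda: int = 50
    folds: int = 10
    min_ratio: float | None = None
    noise_sd: float = 1.0

    def __post_init__(self) -> None:
        if self.name in PRESETS:
            preset = PRESETS[self.name]
            if self.n_train is None:
                object.__setattr__(self, "n_train", preset["n_train"])
            if self.p is None:
                object.__setattr__(self, "p", preset["p"])
        elif self.name != "custom":
            raise ValueError(
                f"unknown scenario {self.name!r}; use "
                f"{sorted(PRESETS)} or 'custom'")
        if self.n_train is None or self.p is None:
            raise ValueError("custom scenarios must set n_train and p")
        unknown = set(self.methods) - set(METHODS)
        if unknown:
            raise ValueError(f"unknown methods: {sorted(unknown)}")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")

    def to_dict(self) -> dict:
        return asdict(self)


def _method_spec(method: str) -> PenaltySpec:
    # benchmark defaults: alpha=0.5, SCAD a=3.7, adaptive gamma=1
    return PenaltySpec(method=method)


def _replicate_seed(master_seed: int, cor_index: int, replicate: int) -> int:
    """Independent substream per (correlation, replicate), < 2**31."""
    ss = np.random.SeedSequence(entropy=master_seed,
                                spawn_key=(cor_index, replicate))
    return int(ss.generate_state(1)[0] % 2**31)


def run_replicate(config: SimulationConfig,
                  methods: tuple[str, ...] = METHODS,
                  replicate: int = 0,
                  n_lambda: int = 50,
                  folds: int = 10,
                  min_ratio: float | None = None) -> list[MetricRecord]:
    """Generate one dataset, tune/fit/evaluate every requested method.

    All methods share the dataset, the lambda grid and the CV fold
    assignment.  A failed fit is logged and skipped rather than aborting.
    """
    data = generate_dataset(config)
    path = lambda_path(data.X_train, data.y_train, n_lambda, min_ratio)
    fold_idx = fold_assignments(len(data.y_train), folds, seed=config.seed)
    records = []
    for method in methods:
        try:
            base = _method_spec(method)
            t0 = time.perf_counter()
            tuned = cross_validate(data.X_train, data.y_train, base, path,
                                   folds=folds, fold_indices=fold_idx)
            result = fit(data.X_train, data.y_train,
                         base.with_lambda(tuned.best_lambda))
            elapsed = time.perf_counter() - t0
            vc, vd = selection_counts(data.beta_true, result.coefficients)
            records.append(MetricRecord(
                method=method,
                cor=config.cor,
                replicate=replicate,
                angle_deg=angle_statistic(data.beta_true, result.coefficients),
                err=test_mse(result.predict(data.X_test), data.y_test),
                vc=vc,
                vd=vd,
                coef_error=coefficient_error(data.beta_true, result.coefficients),
                fit_seconds=elapsed,
            ))
        except Exception:  # noqa: BLE001 - a solver failure must not kill the sweep
            logger.warning("fit failed for %s (cor=%s, replicate=%d); skipped",
                           method, config.cor, replicate, exc_info=True)
    return records


def run_scenario(spec: ScenarioSpec,
                 out_dir: str | Path | None = None,
                 plots: bool = False) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the full correlation sweep; return (replicates, summary) tables.

    When ``out_dir`` is given, writes ``replicates.csv`` and ``summary.csv``
    (and the boxplot/median-curve figures when ``plots`` is set).
    """
    beta = tuple(SimulationConfig(n_train=spec.n_train, p=spec.p,
                                  cor=spec.cor_grid[0],
                                  seed=0).beta)
    n_signal = sum(1 for b in beta if b != 0)
    n_null = spec.p - n_signal
    all_records: list[MetricRecord] = []
    summaries: list[SummaryRow] = []
    for ci, cor in enumerate(spec.cor_grid):
        cell: dict[str, list[MetricRecord]] = {m: [] for m in spec.methods}
        t0 = time.perf_counter()
        for r in range(spec.replicates):
            config = SimulationConfig(
                n_train=spec.n_train, n_test=spec.n_test, p=spec.p, cor=cor,
                noise_sd=spec.noise_sd,
                seed=_replicate_seed(spec.master_seed, ci, r))
            for rec in run_replicate(config, spec.methods, replicate=r,
                                     n_lambda=spec.n_lambda, folds=spec.folds,
                                     min_ratio=spec.min_ratio):
                cell[rec.method].append(rec)
        for method in spec.methods:
            if cell[method]:
                summaries.append(
                    summarize(cell[method], n_signal=n_signal, n_null=n_null))
                all_records.extend(cell[method])
        logger.info("cor=%.2f: %d replicates x %d methods in %.1fs",
                    cor, spec.replicates, len(spec.methods),
                    time.perf_counter() - t0)
    records_df = pd.DataFrame([r.to_dict() for r in all_records])
    summary_df = pd.DataFrame([s.to_dict() for s in summaries])
    if out_dir is not None:
        from .cli import write_results

        write_results(records_df, summary_df, out_dir)
        if plots:
            render_plots(records_df, summary_df, out_dir)
    return records_df, summary_df


def render_plots(records_df: pd.DataFrame, summary_df: pd.DataFrame,
                 out_dir: str | Path) -> list[Path]:
    """Angle/Err boxplots per correlation and the median-vs-cor curves."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    methods = list(dict.fromkeys(records_df["method"]))
    cors = sorted(records_df["cor"].unique())
    for metric, fname in (("angle_deg", "boxplot_angle.png"),
                          ("err", "boxplot_err.png")):
        fig, axes = plt.subplots(1, len(cors), figsize=(3 * len(cors), 4),
                                 sharey=True, squeeze=False)
        for ax, cor in zip(axes[0], cors):
            sub = records_df[records_df["cor"] == cor]
            ax.boxplot([sub.loc[sub["method"] == m, metric].dropna()
                        for m in methods], tick_labels=methods)
            ax.set_title(f"cor={cor}")
            ax.tick_params(axis="x", rotation=60)
        axes[0][0].set_ylabel(metric)
        fig.tight_layout()
        p = out_dir / fname
        fig.savefig(p, dpi=120)
        plt.close(fig)
        paths.append(p)
    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(10, 4))
    for m in methods:
        sub = summary_df[summary_df["method"] == m].sort_values("cor")
        ax1.plot(sub["cor"], sub["angle_median"], marker="o", label=m)
        ax2.plot(sub["cor"], sub["err_median"], marker="o", label=m)
    ax1.set_xlabel("cor"), ax1.set_ylabel("Angle median (deg)")
    ax2.set_xlabel("cor"), ax2.set_ylabel("Err median")
    ax1.legend()
    fig.tight_layout()
    p = out_dir / "median_curves.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    paths.append(p)
    return paths


def fit_csv(table: pd.DataFrame | str | Path, response: str,
            methods: tuple[str, ...] = METHODS,
            split_fraction: float = 0.7, seed: int = 0,
            n_lambda: int = 50, folds: int = 10):
    """Tune and fit each method on a user-supplied tabular dataset.

    All variables (response included) are z-scored with training-split
    statistics, the rows are split train/test by ``split_fraction`` with the
    given seed, lambda is tuned per method by shared-fold K-fold CV, and the
    function returns ``(coefficient_tables, err_table)``: one coefficient
    DataFrame per method (name, estimate; on the standardized-variable
    scale) and a DataFrame of test-set Err per method.
    """
    if not isinstance(table, pd.DataFrame):
        table = pd.read_csv(table)
    if response not in table.columns:
        raise ValueError(f"response column {response!r} not in table")
    if table.isna().any().any():
        bad = table.columns[table.isna().any()].tolist()
        raise ValueError(f"missing values in columns: {bad}")
    for col in table.columns:
        if not np.issubdtype(table[col].dtype, np.number):
            raise ValueError(f"non-numeric column: {col!r}")
    if not (0 < split_fraction < 1):
        raise ValueError("split_fraction must be in (0, 1)")
    n = len(table)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_train = int(round(split_fraction * n))
    if n_train < 2 or n - n_train < 1:
        raise ValueError("split leaves too few rows in one subset")
    train_idx, test_idx = perm[:n_train], perm[n_train:]

    predictors = [c for c in table.columns if c != response]
    X = table[predictors].to_numpy(dtype=float)
    y = table[response].to_numpy(dtype=float)
    # standardize every variable with training statistics
    xm, xs = X[train_idx].mean(axis=0), X[train_idx].std(axis=0)
    xs[xs == 0] = 1.0
    ym, ysd = y[train_idx].mean(), y[train_idx].std()
    if ysd == 0:
        raise ValueError("response is constant on the training split")
    Xz, yz = (X - xm) / xs, (y - ym) / ysd

    path = lambda_path(Xz[train_idx], yz[train_idx], n_lambda)
    fold_idx = fold_assignments(len(train_idx), folds, seed=seed)
    coef_tables: dict[str, pd.DataFrame] = {}
    errs = []
    for method in methods:
        base = _method_spec(method)
        tuned = cross_validate(Xz[train_idx], yz[train_idx], base, path,
                               folds=folds, fold_indices=fold_idx)
        result = fit(Xz[train_idx], yz[train_idx],
                     base.with_lambda(tuned.best_lambda))
        coef_tables[method] = result.to_frame(predictors)
        errs.append({
            "method": method,
            "err": test_mse(result.predict(Xz[test_idx]), yz[test_idx]),
            "lambda": tuned.best_lambda,
            "n_selected": int(np.count_nonzero(result.coefficients)),
        })
    return coef_tables, pd.DataFrame(errs)
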