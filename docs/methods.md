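# Methods

## The problem

`penbench` benchmarks four penalized least-squares estimators — Lasso,
Elastic Net, Adaptive Lasso and SCAD — as variable-selection procedures for
sparse linear models of the kind used in biostatistics and epidemiological
risk modelling (many candidate predictors, few real effects, correlated
exposures). The package generates synthetic replicates with a known sparse
truth, tunes each estimator by cross-validation, and scores the fits on
consistency (the Angle statistic), prediction (test MSE), selection
accuracy (selection/rejection rates) and stability (boxplot outliers).

## Data-generating process

Each replicate draws from the linear random-effects model

    y = X beta + Z delta + eps,    eps ~ N(0, sigma^2 I)

* Rows of `X` are multivariate normal with equicorrelated covariance
  `Sigma(cor)` (unit variances, constant pairwise correlation `cor` in
  [0, 1); `cor = 1` would be exact collinearity and is rejected).
* The column-mean vector `mu ~ N(0, I_p)` is redrawn *per replicate* and
  shared by the train and test splits. These random means are the default
  realization of the random factor: replicate populations differ in level,
  but within a replicate the extra variation is absorbed by the intercept,
  so the irreducible test error remains `sigma^2`. An explicit `Z delta`
  term (`Z` = first `q` columns of `X`, `delta ~ N(0, random_effect_sd^2
  I_q)`) is available via `SimulationConfig(q=..., random_effect_sd=...)`
  and defaults to off (`q = 0`).
* The default truth is `beta = (1, 1.2, -3.2, 4.1, -5, 0 x 45)` with
  `p = 50` and standard-normal noise, so `|S0| = 5` signals, 45 nulls and a
  noise floor of 1 for the test MSE. (The sign of the third coefficient is
  configurable; -3.2 is the default.)
* Scenario presets: `large_sample` (n_train = 2500, p = 50) and `high_dim`
  (n_train = 40, p = 50). The test split defaults to the training size.
  Replicate seeds are spawned from a single master seed via
  `numpy.random.SeedSequence`, so any replicate is reproducible in
  isolation and the whole sweep is a pure function of its spec.

What the generator does **not** emulate: non-Gaussian designs, AR(1) or
block correlation, heteroscedastic or heavy-tailed noise, missingness.
Passing benchmarks here says nothing about robustness to those features.

## Estimators

All four minimize `(1/2n)||y - b0 - X b||^2 + P(b)` with predictors
internally centered/scaled to unit variance and the response centered;
coefficients are reported back-transformed with the intercept recovered.
The `1/2n` loss scaling keeps one lambda grid meaningful across sample
sizes (a penalty quoted against the raw RSS maps via
`lambda_here = lambda_rss / 2n`).

* **Lasso** `P = lambda sum |b_j|` and **Elastic Net**
  `P = lambda [(1-alpha) sum |b_j| + alpha sum b_j^2]` share a cyclic
  coordinate-descent core on the Gram matrix `G = X'X/n` (the per-sweep
  cost is then independent of `n`, which matters at n = 2500 x 10 folds x
  50 path points). Note `alpha` here is the *ridge share*: `alpha = 0` is
  the lasso, `alpha = 1` ridge; the benchmark default is 0.5.
* **Adaptive Lasso** uses weights `w_j = 1/|b_init_j|^gamma` (default
  `gamma = 1`) with `b_init` the OLS fit when n > p and a small-ridge fit
  (penalty 1e-3 on the internal scale) otherwise; zero initial estimates
  are capped at `w = 1e8`, effectively excluding the coordinate.
* **SCAD** (`a = 3.7`) is solved by iterating the local quadratic
  approximation: each penalty term is majorized at the current iterate by a
  quadratic with curvature `P'(|b_j|)/|b_j|`, the generalized ridge system
  is solved on the active set, coordinates falling below 1e-6 are zeroed
  and permanently dropped, and the loop repeats from the OLS/ridge initial
  estimate at every lambda. This is a majorize-minimize scheme: the
  objective is non-increasing, and the limit is a stationary point that
  need not be the global optimum of the non-convex objective.

Numerical choices: convergence is declared when the largest coefficient
update, relative to the largest coefficient magnitude (floored at 1),
drops below 1e-6; coordinate descent allows 10,000 sweeps. The LQA outer
loop allows 500 iterations — near a soft-threshold fixed point the
majorizer contracts geometrically with a factor that can approach 1, and a
smaller cap leaves coefficients that are en route to zero stranded above
the drop threshold, corrupting selection counts (the 1-D grid-search
oracle agrees with the converged LQA to 1e-3). Near-singular LQA systems
get a 1e-12 ridge jitter. Coordinate order is cyclic 1..p, deterministic.

## Tuning

The lambda grid is log-spaced over 50 values from
`lambda_max = max_j |x_j'y|/n` (the smallest penalty with an all-zero
solution) down to `lambda_max * min_ratio`, with `min_ratio = 0.001` for
n > p and `0.05` for n <= p. The primary selector is 10-fold
cross-validation with the minimum-mean-MSE rule (no one-standard-error
rule); folds are seeded, shuffled, and shared across methods within a
replicate so comparisons are paired. GCV — `RSS/(n (1 - df/n)^2)` with
`df` = active-set size + 1 — is provided as an alternative selector; the
df convention is a documented choice, since path algorithms differ in how
they count degrees of freedom.

## Evaluation

* **Angle**: `(180/pi) arccos(<b, bhat>)` after unit-normalizing both
  vectors; 0 means perfect directional agreement. A zero estimate has no
  direction: the Angle is recorded as missing, excluded from medians and
  counted (`n_angle_missing`), rather than imputed as 90.
* **Err**: test-split mean squared prediction error; its expectation is
  bounded below by the noise variance (1 by default).
* **VC / VD**: counts of true signals retained and true nulls eliminated,
  with a zero tolerance of 1e-8 on the original coefficient scale
  (coordinate descent produces exact zeros; the tolerance only guards
  float dust). Summaries report them as selection and rejection rates.
* **Stability**: Tukey boxplot outlier counts (1.5 IQR fences, quartiles
  by linear interpolation) of Angle and Err across replicates; reported as
  missing below 4 usable values.
* **Coefficient error**: mean absolute deviation `(1/p) sum |bhat - b|` by
  default (RMSE and l2 norm are available) — the reading most consistent
  with the magnitudes this metric is typically reported at.
* Summaries use medians for Angle and Err (robust to wild replicates) and
  means for counts, times and coefficient error.

## Problem sizes used by the shipped runs

The acceptance script and the end-to-end tests run the large-sample sweep
at m = 50 replicates per correlation and the high-dimensional sweep at
m = 300, with 50-point lambda paths and 10-fold CV throughout — sizes at
which every cell's Monte-Carlo standard error is a small fraction of the
effects being checked, while a full run stays in the minutes range on one
core.

## Known limitations and observed behavior

* The selection behavior of CV-min-tuned fits is selector-specific. With
  the minimum-MSE rule at n >> p the CV curve is nearly flat over a wide
  lambda range, so the lasso's rejection rate (fraction of nulls dropped)
  lands wherever the noisy argmin falls — here typically 70–80% at
  cor = 0.6 — while SCAD, whose flat penalty region makes large lambdas
  costless for the signals, rejects essentially all nulls. GCV-based
  selection shifts both numbers.
* The elastic net at `alpha = 0.5` retains nearly all predictors (its
  grouping behavior); its test MSE therefore carries an OLS-like variance
  excess of roughly `p/n_train` above the noise floor — at n = 2500,
  p = 50 about 1.02 — which no amount of tuning removes under this mixing
  convention.
* With exactly duplicated predictors the l1 solution is unique only in the
  pair sum; cyclic coordinate descent returns one arbitrary optimal split.
  The elastic net's strictly convex penalty splits such pairs exactly
  evenly.
* SCAD's LQA is a local method: with correlated designs and small lambda
  it can converge to different stationary points across replicates, which
  is visible as the largest Angle/Err outlier counts among the four
  methods.
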