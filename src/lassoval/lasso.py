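"""Penalized linear model fitting, penalty tuning and cross-imputation pooling.

The model minimises ``(1/2n)*RSS + lam*||beta||_1`` with covariates
standardised internally (unit population variance) and an unpenalised
intercept; reported coefficients are on the original covariate scale, so the
penalty magnitudes are directly comparable with glmnet-style software.

Tuning follows the bootstrap-corrected-MSE recipe: models are fit on
bootstrap resamples (with replacement, same size) over a descending penalty
grid and scored on the rows each resample left out (out-of-bag, the
behaviour of caret-style bootstrap resampling; scoring on the full original
sample is available as an option).  The "best" penalty minimises the mean
bootstrap MSE, and the "tolerance" penalty is the strongest penalty whose
mean MSE stays within a 3% band of that minimum, trading a little accuracy
for parsimony.

With multiply imputed data the penalty is tuned and the model fit separately
per completed set, and the final model averages the coefficient vectors
element-wise (a covariate selected in only one of M sets keeps 1/M of its
value).  The tuning bootstrap index stream depends only on (seed, n), i.e. it
is shared across imputed sets, so M identical copies pool to exactly the
single-set fit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import Dataset, as_imputed_sets
from .solver import cd_path, lambda_max, path_on_data, standardize

MODES = ("best", "tolerance")
DEFAULT_N_LAMBDA = 40
DEFAULT_N_BOOT = 100
DEFAULT_TOLERANCE = 0.03
GRID_DECADES = 3.0


@dataclass
class LassoModel:
    """A single fitted L1-penalised linear model."""

    intercept: float
    coefficients: np.ndarray        # original covariate scale
    penalty: float
    center: np.ndarray
    scale: np.ndarray

    def __post_init__(self) -> None:
        if self.penalty < 0:
            raise ValueError("penalty must be non-negative")
        self.coefficients = np.asarray(self.coefficients, dtype=float)

    def predict(self, X) -> np.ndarray:
        X = X.covariates if isinstance(X, Dataset) else np.asarray(X, dtype=float)
        return self.intercept + X @ self.coefficients

    @property
    def coefficients_std(self) -> np.ndarray:
        """Coefficients on the internally standardised scale."""
        return self.coefficients * self.scale

    def n_selected(self) -> int:
        return int(np.count_nonzero(self.coefficients))


@dataclass
class TuningResult:
    grid: np.ndarray
    mean_boot_mse: np.ndarray
    best_lambda: float
    tolerance_lambda: float
    n_boot: int
    tolerance_fraction: float = DEFAULT_TOLERANCE

    def lambda_for(self, mode: str) -> float:
        if mode == "best":
            return self.best_lambda
        if mode == "tolerance":
            return self.tolerance_lambda
        raise ValueError(f"unknown mode {mode!r}")


@dataclass
class PooledLassoModel:
    """Element-wise average of M per-imputation lasso fits."""

    intercept: float
    coefficients: np.ndarray
    selection_counts: np.ndarray    # imputations in which each covariate was nonzero
    models: list[LassoModel] | None = None
    tunings: list[TuningResult] | None = None
    mode: str | None = None
    columns: list[str] | None = None

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        self.selection_counts = np.asarray(self.selection_counts, dtype=int)

    @property
    def m(self) -> int:
        return len(self.models) if self.models is not None else 1

    def predict(self, X) -> np.ndarray:
        X = X.covariates if isinstance(X, Dataset) else np.asarray(X, dtype=float)
        return self.intercept + X @ self.coefficients

    @property
    def lambdas(self) -> list[float] | None:
        if self.models is None:
            return None
        return [m.penalty for m in self.models]

    def selected(self, min_count: int = 1) -> np.ndarray:
        """Boolean per-covariate: retained in at least ``min_count`` sets."""
        return self.selection_counts >= min_count

    def scaled(self, factor: float) -> "PooledLassoModel":
        """Slopes multiplied by ``factor``; intercept untouched (re-estimate
        it with :func:`lassoval.performance.recalibrate`)."""
        return PooledLassoModel(
            intercept=self.intercept,
            coefficients=self.coefficients * factor,
            selection_counts=self.selection_counts.copy(),
            models=self.models,
            tunings=self.tunings,
            mode=self.mode,
            columns=self.columns,
        )


def fit_lasso(X, y=None, lam: float | None = None) -> LassoModel:
    """Fit the penalised model at a single penalty value.

    Accepts either ``fit_lasso(X, y, lam)`` with arrays or
    ``fit_lasso(dataset, lam)``.  Degenerate inputs: a constant outcome
    yields an intercept-only model; a zero-variance covariate keeps
    coefficient 0.
    """
    if isinstance(X, Dataset):
        if lam is None:
            lam, y = y, None
        X, y = X.covariates, X.outcome
    if lam is None or y is None:
        raise TypeError("fit_lasso needs (X, y, lam) or (dataset, lam)")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-d covariate matrix with at least 2 rows")
    if np.isnan(X).any() or np.isnan(y).any():
        raise ValueError("fit_lasso requires complete data")
    if lam < 0:
        raise ValueError("penalty must be non-negative")
    n = X.shape[0]
    Xs, center, scale, _ = standardize(X)
    ybar = float(y.mean())
    if np.all(y == y[0]):
        return LassoModel(ybar, np.zeros(X.shape[1]), lam, center, scale)
    coefs_std = cd_path(Xs.T @ Xs / n, Xs.T @ (y - ybar) / n, np.array([lam]))[0]
    coefs = coefs_std / scale
    return LassoModel(ybar - float(coefs @ center), coefs, lam, center, scale)


def make_penalty_grid(X, y=None, n_lambda: int = DEFAULT_N_LAMBDA) -> np.ndarray:
    """Descending log-spaced penalty grid over ``GRID_DECADES`` decades.

    The top of the grid is the smallest penalty that shrinks every slope to
    zero, ``max_j |x~_j'(y - ybar)| / n`` on standardised covariates.
    """
    if isinstance(X, Dataset):
        X, y = X.covariates, X.outcome
    if n_lambda < 1:
        raise ValueError("n_lambda must be >= 1")
    lmax = lambda_max(np.asarray(X, float), np.asarray(y, float))
    if lmax <= 0:
        raise ValueError("degenerate data: lambda_max is zero")
    if n_lambda == 1:
        return np.array([lmax])
    return np.geomspace(lmax, lmax * 10.0 ** (-GRID_DECADES), n_lambda)


def _boot_indices(rng: np.random.Generator, n: int, n_boot: int) -> np.ndarray:
    return rng.integers(0, n, size=(n_boot, n))


def tune_penalty(
    data,
    grid: np.ndarray | None = None,
    n_boot: int = DEFAULT_N_BOOT,
    seed=None,
    n_lambda: int = DEFAULT_N_LAMBDA,
    tolerance_fraction: float = DEFAULT_TOLERANCE,
    scoring: str = "oob",
) -> TuningResult:
    """Bootstrap-corrected-MSE tuning of the penalty over a grid.

    For each of ``n_boot`` resamples (shared across the whole grid) the full
    path is fit on the resample and scored by MSE on held-out data: with
    ``scoring="oob"`` (default, the behaviour of caret-style bootstrap
    resampling) on the rows left out of the resample, with
    ``scoring="original"`` on the complete original sample.  Ties in the
    argmin break toward the stronger penalty.
    """
    if isinstance(data, Dataset):
        data.require_complete("tune_penalty")
        X, y = data.covariates, data.outcome
    else:
        X, y = data
        X = np.asarray(X, float)
        y = np.asarray(y, float)
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    if grid is None:
        grid = make_penalty_grid(X, y, n_lambda)
    grid = np.asarray(grid, dtype=float)
    if np.any(np.diff(grid) > 0):
        raise ValueError("penalty grid must be descending")

    if scoring not in ("oob", "original"):
        raise ValueError("scoring must be 'oob' or 'original'")
    n = X.shape[0]
    rng = np.random.default_rng(seed)
    idx = _boot_indices(rng, n, n_boot)
    mse = np.empty((n_boot, grid.size))
    for bi in range(n_boot):
        coefs, intercepts = path_on_data(X[idx[bi]], y[idx[bi]], grid)
        if scoring == "oob":
            rows = np.setdiff1d(np.arange(n), idx[bi])
            if rows.size == 0:  # resample covered every row; score on all
                rows = np.arange(n)
        else:
            rows = np.arange(n)
        resid = y[rows, None] - (X[rows] @ coefs.T + intercepts)
        mse[bi] = np.mean(resid**2, axis=0)
    mean_mse = mse.mean(axis=0)
    best_i = int(np.argmin(mean_mse))          # first occurrence = largest lambda
    cutoff = (1.0 + tolerance_fraction) * mean_mse[best_i]
    tol_i = int(np.flatnonzero(mean_mse <= cutoff)[0])  # strongest penalty within band
    return TuningResult(grid, mean_mse, float(grid[best_i]), float(grid[tol_i]),
                        n_boot, tolerance_fraction)


def pool_models(models: list[LassoModel], mode: str | None = None,
                columns: list[str] | None = None,
                tunings: list[TuningResult] | None = None) -> PooledLassoModel:
    """Average intercepts and coefficient vectors element-wise (zeros count)."""
    if not models:
        raise ValueError("nothing to pool")
    coef = np.mean([m.coefficients for m in models], axis=0)
    intercept = float(np.mean([m.intercept for m in models]))
    counts = np.sum([m.coefficients != 0 for m in models], axis=0)
    return PooledLassoModel(intercept, coef, counts, list(models), tunings, mode, columns)


def fit_pooled(
    imputed_sets,
    mode="best",
    n_lambda: int = DEFAULT_N_LAMBDA,
    n_boot: int = DEFAULT_N_BOOT,
    seed=None,
    tolerance_fraction: float = DEFAULT_TOLERANCE,
    scoring: str = "oob",
):
    """Tune and fit per imputed set, then average coefficients.

    ``mode`` may be ``"best"``, ``"tolerance"`` or a sequence of modes; with a
    sequence a dict of pooled models sharing one tuning pass is returned.
    Each set is tuned with the same bootstrap index stream (see module note).
    """
    sets = as_imputed_sets(imputed_sets)
    modes = (mode,) if isinstance(mode, str) else tuple(mode)
    for md in modes:
        if md not in MODES:
            raise ValueError(f"unknown mode {md!r}")
    seed_tune = np.random.SeedSequence(seed) if not isinstance(seed, np.random.SeedSequence) else seed

    tunings: list[TuningResult] = []
    per_mode: dict[str, list[LassoModel]] = {md: [] for md in modes}
    for ds in sets:
        # same SeedSequence (not an advancing Generator) => identical
        # bootstrap indices for every set
        tr = tune_penalty(ds, n_boot=n_boot, seed=seed_tune,
                          n_lambda=n_lambda, tolerance_fraction=tolerance_fraction,
                          scoring=scoring)
        tunings.append(tr)
        for md in modes:
            per_mode[md].append(fit_lasso(ds, tr.lambda_for(md)))
    pooled = {
        md: pool_models(per_mode[md], md, sets.columns[:-1], tunings) for md in modes
    }
    return pooled[modes[0]] if isinstance(mode, str) else pooled
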