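"""Multiple imputation by chained equations.

Conventions: continuous columns are imputed by predictive mean matching
(PMM), binary columns by draws from a logistic model; every other column —
including the outcome — serves as a predictor.  Each of the M imputations
runs on an independent random substream; within one imputation the
incomplete columns are visited in order of increasing missingness for
``n_cycles`` chained sweeps, starting from random draws out of each column's
observed values.

Parameter uncertainty is injected the "approximately proper" way: linear
sub-models draw the residual variance from its scaled inverse chi-square
distribution and the coefficients from their resulting normal sampling
distribution; logistic sub-models draw coefficients from the asymptotic
normal around the fit.  PMM then matches each missing case's perturbed
prediction to the ``k`` observed cases with closest (unperturbed) predicted
values and copies one donor's observed value, so imputed continuous values
are always members of the observed support.
"""

from __future__ import annotations

import logging

import numpy as np

from .data import BINARY, Dataset, ImputedSets

logger = logging.getLogger(__name__)

DEFAULT_M = 10
DEFAULT_CYCLES = 5
DEFAULT_DONORS = 5


def pmm_draw(
    observed_outcome: np.ndarray,
    observed_predictions: np.ndarray,
    missing_predictions: np.ndarray,
    k: int = DEFAULT_DONORS,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Predictive-mean-matching donor draw.

    For each missing case, locate the ``k`` observed cases whose predicted
    values are closest to the missing case's prediction and copy the observed
    outcome of one donor chosen at random.  With fewer than ``k`` observed
    cases all of them serve as donors.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    rng = np.random.default_rng(rng)
    obs_y = np.asarray(observed_outcome, dtype=float)
    obs_p = np.asarray(observed_predictions, dtype=float)
    mis_p = np.asarray(missing_predictions, dtype=float)
    if obs_y.shape != obs_p.shape:
        raise ValueError("observed outcomes and predictions differ in length")
    k_eff = min(k, obs_y.size)
    dist = np.abs(obs_p[None, :] - mis_p[:, None])
    donors = np.argpartition(dist, k_eff - 1, axis=1)[:, :k_eff]
    pick = rng.integers(0, k_eff, size=mis_p.size)
    return obs_y[donors[np.arange(mis_p.size), pick]]


def _irls_logistic(y: np.ndarray, X: np.ndarray, ridge: float, max_iter: int = 30):
    """Newton/IRLS logistic fit with an L2 stabiliser on the normal
    equations; returns (coef, cov) or None if it failed to converge."""
    p = X.shape[1]
    coef = np.zeros(p)
    eye = np.eye(p)
    for _ in range(max_iter):
        eta = np.clip(X @ coef, -30, 30)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        H = X.T @ (w[:, None] * X) + ridge * eye
        g = X.T @ (y - mu) - ridge * coef
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            return None
        coef = coef + step
        if not np.isfinite(coef).all() or np.abs(coef).max() > 1e6:
            return None
        if np.abs(step).max() < 1e-8:
            return coef, np.linalg.inv(H)
    return None


def _fit_logistic(y: np.ndarray, X: np.ndarray):
    """Logistic fit for one imputation sub-model.

    Near-MLE IRLS with a tiny ridge (matches statsmodels GLM to ~1e-6 on
    well-conditioned data; see tests); under separation the ridge is
    escalated until the fit stabilises, with a logged warning.  Returns
    (coef, cov); cov is None when only the heavily ridged fit converged.
    """
    n = X.shape[0]
    fit = _irls_logistic(y, X, ridge=1e-6 * n)
    if fit is not None and np.abs(fit[0]).max() < 25:
        return fit
    logger.warning("logistic imputation model unstable; using ridge-stabilised fit")
    for ridge in (0.1 * n, n, 10.0 * n):
        fit = _irls_logistic(y, X, ridge=ridge)
        if fit is not None:
            return fit[0], None
    return np.zeros(X.shape[1]), None


def logistic_draw(
    observed_binary: np.ndarray,
    predictors_observed: np.ndarray,
    predictors_missing: np.ndarray,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Impute a binary column via a logistic model with parameter draws.

    Fits on the observed cases (intercept added), perturbs the coefficients
    by one draw from their asymptotic normal distribution, and imputes each
    missing case as Bernoulli of its fitted probability.  With a single
    observed class the fit is degenerate and that class is imputed throughout
    (with a logged warning).
    """
    rng = np.random.default_rng(rng)
    y = np.asarray(observed_binary, dtype=float)
    X_obs = np.column_stack([np.ones(len(y)), np.asarray(predictors_observed, float)])
    X_mis = np.column_stack(
        [np.ones(len(predictors_missing)), np.asarray(predictors_missing, float)]
    )
    classes = np.unique(y)
    if classes.size < 2:
        logger.warning("binary column has a single observed level; imputing that level")
        return np.full(X_mis.shape[0], classes[0] if classes.size else 0.0)
    coef, cov = _fit_logistic(y, X_obs)
    if cov is not None:
        coef = rng.multivariate_normal(coef, cov, method="cholesky")
    prob = 1.0 / (1.0 + np.exp(-np.clip(X_mis @ coef, -30, 30)))
    return (rng.random(X_mis.shape[0]) < prob).astype(float)


def _linear_pmm_column(y_obs, X_obs, X_mis, k, rng):
    """PMM with a Bayesian-perturbed linear sub-model (mice 'type 1' matching:
    observed predictions use the MLE, missing predictions the perturbed
    coefficients)."""
    n, p = X_obs.shape
    coef, _, rank, _ = np.linalg.lstsq(X_obs, y_obs, rcond=None)
    resid = y_obs - X_obs @ coef
    dof = max(n - rank, 1)
    sigma2_star = float(resid @ resid) / max(rng.chisquare(dof), 1e-12)
    XtX = X_obs.T @ X_obs + 1e-10 * np.eye(p)
    cov = sigma2_star * np.linalg.inv(XtX)
    coef_star = rng.multivariate_normal(coef, (cov + cov.T) / 2.0, method="svd")
    return pmm_draw(y_obs, X_obs @ coef, X_mis @ coef_star, k=k, rng=rng)


def impute(
    dataset: Dataset,
    m: int = DEFAULT_M,
    n_cycles: int = DEFAULT_CYCLES,
    pmm_donors: int = DEFAULT_DONORS,
    seed=None,
) -> ImputedSets:
    """Chained-equations multiple imputation of ``dataset``.

    Returns M completed copies; observed cells are identical across copies
    and equal the source values.  A complete dataset yields M identical
    copies.  A column with no observed values is an error.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    if n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")
    n_missing = (~dataset.mask).sum(axis=0)
    if not (n_missing == 0).any():
        raise ValueError("chained equations need at least one fully observed column")
    for j, nm in enumerate(n_missing):
        if nm == dataset.n:
            raise ValueError(f"column {dataset.columns[j]!r} has no observed values")

    incomplete = np.flatnonzero(n_missing > 0)
    incomplete = incomplete[np.argsort(n_missing[incomplete], kind="stable")]

    root = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    streams = root.spawn(m)

    sets: list[Dataset] = []
    for i in range(m):
        rng = np.random.default_rng(streams[i])
        vals = dataset.values.copy()
        # start from random draws out of each column's observed values
        for j in incomplete:
            obs = dataset.values[dataset.mask[:, j], j]
            mis_rows = ~dataset.mask[:, j]
            vals[mis_rows, j] = rng.choice(obs, size=int(mis_rows.sum()), replace=True)
        for _ in range(n_cycles):
            for j in incomplete:
                obs_rows = dataset.mask[:, j]
                mis_rows = ~obs_rows
                others = [c for c in range(vals.shape[1]) if c != j]
                X_obs = vals[np.ix_(obs_rows, others)]
                X_mis = vals[np.ix_(mis_rows, others)]
                y_obs = vals[obs_rows, j]
                if dataset.var_types[j] == BINARY:
                    vals[mis_rows, j] = logistic_draw(y_obs, X_obs, X_mis, rng=rng)
                else:
                    X_obs1 = np.column_stack([np.ones(X_obs.shape[0]), X_obs])
                    X_mis1 = np.column_stack([np.ones(X_mis.shape[0]), X_mis])
                    vals[mis_rows, j] = _linear_pmm_column(
                        y_obs, X_obs1, X_mis1, pmm_donors, rng
                    )
        sets.append(
            Dataset(vals, np.ones_like(vals, dtype=bool), list(dataset.columns),
                    list(dataset.var_types))
        )
    seed_int = None if isinstance(seed, np.random.SeedSequence) else seed
    return ImputedSets(sets, dataset.mask.copy(), seed_int)


def drop_imputed_outcome_rows(imputed: ImputedSets) -> ImputedSets:
    """Exclude rows whose outcome was itself imputed (optional analysis
    filter; inert when outcomes are completely observed)."""
    keep = imputed.source_mask[:, -1]
    if keep.all():
        return imputed
    sets = [
        Dataset(ds.values[keep], ds.mask[keep], list(ds.columns), list(ds.var_types))
        for ds in imputed
    ]
    return ImputedSets(sets, imputed.source_mask[keep], imputed.seed)
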