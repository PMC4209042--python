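"""Discrimination (MSE) and calibration of a fitted prediction model.

Calibration regresses the observed outcome on the model's linear predictor,
``y = a_LP + b_LP * LP``; a perfectly calibrated model has intercept 0 and
slope 1, while a slope above 1 signals over-shrunk predictions (too narrow a
prediction range).  A decile table of mean predicted vs mean observed
outcome is reported alongside, each decile flagged against a +/-0.5 band of
clinically negligible miscalibration.  Recalibration multiplies every slope
coefficient by a uniform shrinkage factor and re-estimates the intercept so
the mean prediction matches the mean observed outcome.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import Dataset, as_imputed_sets
from .lasso import PooledLassoModel

CLINICAL_BAND = 0.5


@dataclass
class CalibrationResult:
    intercept_lp: float
    slope_lp: float
    decile_table: pd.DataFrame       # columns: mean_predicted, mean_observed, n, within_band
    n_bins: int

    @property
    def within_band(self) -> np.ndarray:
        return self.decile_table["within_band"].to_numpy()


def mse(model, dataset: Dataset) -> float:
    """Mean squared residual of ``model`` on a complete dataset."""
    dataset.require_complete("mse")
    resid = dataset.outcome - model.predict(dataset)
    return float(np.mean(resid**2))


def apparent_performance(model, imputed_sets, exclude_imputed_outcomes: bool = False) -> float:
    """MSE of one (pooled) model on each completed set, averaged over sets."""
    sets = as_imputed_sets(imputed_sets)
    if exclude_imputed_outcomes:
        from .impute import drop_imputed_outcome_rows

        sets = drop_imputed_outcome_rows(sets)
    return float(np.mean([mse(model, ds) for ds in sets]))


def _ols_line(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    vx = x.var()
    if vx <= 0:
        raise ValueError("linear predictor is constant; calibration slope undefined")
    slope = float(np.cov(x, y, ddof=0)[0, 1] / vx)
    return float(y.mean() - slope * x.mean()), slope


def calibration(model, dataset: Dataset, n_bins: int = 10) -> CalibrationResult:
    """Calibration line and decile table of ``model`` on ``dataset``.

    Bin edges are sample quantiles of the predictions; a prediction equal to
    an edge joins the lower bin.
    """
    dataset.require_complete("calibration")
    pred = model.predict(dataset)
    obs = dataset.outcome
    intercept, slope = _ols_line(pred, obs)

    edges = np.quantile(pred, np.linspace(0, 1, n_bins + 1)[1:-1])
    bins = np.searchsorted(edges, pred, side="left")
    rows = []
    for b in range(n_bins):
        in_bin = bins == b
        if not in_bin.any():
            rows.append((np.nan, np.nan, 0, True))
            continue
        mp, mo = float(pred[in_bin].mean()), float(obs[in_bin].mean())
        rows.append((mp, mo, int(in_bin.sum()), bool(abs(mp - mo) <= CLINICAL_BAND)))
    table = pd.DataFrame(rows, columns=["mean_predicted", "mean_observed", "n", "within_band"])
    table.index.name = "decile"
    return CalibrationResult(intercept, slope, table, n_bins)


def pooled_calibration_slope(model, imputed_sets) -> float:
    """Calibration slope averaged over the completed sets."""
    sets = as_imputed_sets(imputed_sets)
    return float(np.mean([_ols_line(model.predict(ds), ds.outcome)[1] for ds in sets]))


def recalibrate(pooled_model: PooledLassoModel, shrinkage_s: float, imputed_sets) -> PooledLassoModel:
    """Uniform-shrinkage recalibration.

    Every slope coefficient is multiplied by ``shrinkage_s`` and the
    intercept re-estimated so that the mean prediction equals the mean
    observed outcome, averaged over the completed sets.
    """
    if not np.isfinite(shrinkage_s) or shrinkage_s <= 0:
        raise ValueError("shrinkage factor must be finite and positive")
    sets = as_imputed_sets(imputed_sets)
    scaled = pooled_model.scaled(shrinkage_s)
    offsets = [
        float(ds.outcome.mean() - (ds.covariates @ scaled.coefficients).mean()) for ds in sets
    ]
    scaled.intercept = float(np.mean(offsets))
    return scaled
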