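"""Model/Results facade over the functional layer.

``PrognosticLasso`` is constructed from data (a complete ``Dataset``, an
``ImputedSets``, a pandas DataFrame, or an incomplete ``Dataset`` which is
multiply imputed at construction); ``fit()`` tunes the penalty by the
bootstrap-corrected MSE per completed set, fits, pools, and returns a
``PrognosticLassoResults`` carrying the averaged coefficients, selection
counts, tuning profiles, and the performance/validation methods.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .data import Dataset, ImputedSets, read_dataset
from .impute import DEFAULT_CYCLES, DEFAULT_DONORS, DEFAULT_M, impute
from .lasso import (DEFAULT_N_BOOT, DEFAULT_N_LAMBDA, DEFAULT_TOLERANCE,
                    PooledLassoModel, fit_pooled)
from .performance import (CalibrationResult, apparent_performance, calibration,
                          mse, pooled_calibration_slope, recalibrate)
from .validation import ValidationReport, bootstrap_optimism


class PrognosticLasso:
    """Lasso prediction model on (possibly multiply imputed) data.

    Parameters
    ----------
    data : Dataset | ImputedSets | pandas.DataFrame
        Analysis data.  An incomplete ``Dataset`` (or DataFrame with NaNs)
        is multiply imputed here, keeping the incomplete original for
        approach-4 validation.
    m, n_cycles, pmm_donors : imputation settings (used only when the input
        is incomplete).
    seed : master seed; the imputation stream is spawned from it.
    """

    def __init__(self, data, m: int = DEFAULT_M, n_cycles: int = DEFAULT_CYCLES,
                 pmm_donors: int = DEFAULT_DONORS, seed=None):
        self._seed = seed
        self._root = np.random.SeedSequence(seed)
        self._s_imp, self._s_fit_default = self._root.spawn(2)
        self.impute_settings = dict(m=m, n_cycles=n_cycles, pmm_donors=pmm_donors)
        if isinstance(data, pd.DataFrame):
            vals = data.to_numpy(dtype=float)
            data = Dataset(np.nan_to_num(vals), ~np.isnan(vals), list(data.columns),
                           _infer_types(vals, ~np.isnan(vals)))
        if isinstance(data, ImputedSets):
            self.incomplete: Dataset | None = None
            self.imputed = data
        elif isinstance(data, Dataset):
            if data.is_complete:
                self.incomplete = None
                self.imputed = ImputedSets([data], data.mask.copy())
            else:
                self.incomplete = data
                self.imputed = impute(data, m=m, n_cycles=n_cycles,
                                      pmm_donors=pmm_donors, seed=self._s_imp)
        else:
            raise TypeError(f"unsupported data type {type(data).__name__}")

    @classmethod
    def from_csv(cls, path, types_path=None, **kwargs) -> "PrognosticLasso":
        return cls(read_dataset(path, types_path), **kwargs)

    @property
    def columns(self) -> list[str]:
        return self.imputed.columns

    def fit(self, mode: str = "best", n_lambda: int = DEFAULT_N_LAMBDA,
            n_boot: int = DEFAULT_N_BOOT,
            tolerance_fraction: float = DEFAULT_TOLERANCE,
            seed=None) -> "PrognosticLassoResults":
        fit_seed = self._s_fit_default if seed is None else np.random.SeedSequence(seed)
        pooled = fit_pooled(self.imputed, mode, n_lambda=n_lambda, n_boot=n_boot,
                            seed=fit_seed, tolerance_fraction=tolerance_fraction)
        return PrognosticLassoResults(self, pooled, dict(
            mode=mode, n_lambda=n_lambda, n_boot=n_boot,
            tolerance_fraction=tolerance_fraction))


class PrognosticLassoResults:
    """Fitted pooled lasso model plus its performance/validation surface."""

    def __init__(self, model: PrognosticLasso, pooled: PooledLassoModel, settings: dict):
        self.model = model
        self.pooled = pooled
        self.settings = settings

    # -- estimates -----------------------------------------------------
    @property
    def params(self) -> pd.Series:
        names = ["intercept"] + list(self.model.columns[:-1])
        return pd.Series([self.pooled.intercept, *self.pooled.coefficients], index=names)

    @property
    def selection_counts(self) -> pd.Series:
        return pd.Series(self.pooled.selection_counts, index=self.model.columns[:-1])

    @property
    def lambdas(self) -> list[float]:
        return self.pooled.lambdas or []

    def predict(self, X) -> np.ndarray:
        return self.pooled.predict(X)

    # -- performance ---------------------------------------------------
    def apparent_mse(self) -> float:
        return apparent_performance(self.pooled, self.model.imputed)

    def mse(self, dataset: Dataset) -> float:
        return mse(self.pooled, dataset)

    def calibration(self, dataset: Dataset | None = None, n_bins: int = 10) -> CalibrationResult:
        ds = dataset if dataset is not None else self.model.imputed.sets[0]
        return calibration(self.pooled, ds, n_bins=n_bins)

    def calibration_slope(self) -> float:
        return pooled_calibration_slope(self.pooled, self.model.imputed)

    def validate(self, approach: int = 1, B: int = 100, seed=None,
                 **kwargs) -> ValidationReport:
        src = self.model.incomplete if approach == 4 else self.model.imputed
        if approach == 4 and src is None:
            raise ValueError("approach 4 needs the incomplete source data")
        for key, val in (("n_lambda", self.settings["n_lambda"]),
                         ("n_boot_tune", self.settings["n_boot"]),
                         ("tolerance_fraction", self.settings["tolerance_fraction"])):
            kwargs.setdefault(key, val)
        if approach == 4:
            kwargs.setdefault("original_sets", self.model.imputed)
            kwargs.setdefault("m", self.model.imputed.m)
            kwargs.setdefault("impute_kwargs", {
                k: v for k, v in self.model.impute_settings.items() if k != "m"})
        return bootstrap_optimism(src, approach, B=B, mode=self.settings["mode"],
                                  seed=seed, apparent=self.apparent_mse(), **kwargs)

    def recalibrate(self, shrinkage_s: float) -> "PrognosticLassoResults":
        scaled = recalibrate(self.pooled, shrinkage_s, self.model.imputed)
        return PrognosticLassoResults(self.model, scaled,
                                      dict(self.settings, shrinkage_s=shrinkage_s))

    # -- presentation --------------------------------------------------
    def summary(self) -> str:
        from statsmodels.iolib.table import SimpleTable

        head = [
            ("model:", "pooled lasso"),
            ("mode:", str(self.settings["mode"])),
            ("imputations:", str(self.model.imputed.m)),
            ("n obs:", str(self.model.imputed.sets[0].n)),
            ("penalty grid:", str(self.settings["n_lambda"])),
            ("tuning bootstraps:", str(self.settings["n_boot"])),
            ("apparent MSE:", f"{self.apparent_mse():.4f}"),
            ("calibration slope:", f"{self.calibration_slope():.4f}"),
        ]
        info = SimpleTable([[k, v] for k, v in head], title="Pooled Lasso Results")
        rows = [["intercept", f"{self.pooled.intercept:.6g}", ""]]
        for name, coef, cnt in zip(self.model.columns[:-1],
                                   self.pooled.coefficients,
                                   self.pooled.selection_counts):
            if coef != 0 or cnt > 0:
                rows.append([name, f"{coef:.6g}", str(int(cnt))])
        coefs = SimpleTable(rows, headers=["covariate", "pooled coef", f"selected (of {self.model.imputed.m})"])
        return str(info) + "\n" + str(coefs)

    def to_dict(self) -> dict:
        return {
            "intercept": float(self.pooled.intercept),
            "coefficients": self.pooled.coefficients.tolist(),
            "columns": list(self.model.columns),
            "selection_counts": self.pooled.selection_counts.tolist(),
            "lambdas": self.lambdas,
            "settings": self.settings,
            "tuning_profiles": [
                {"grid": t.grid.tolist(), "mean_boot_mse": t.mean_boot_mse.tolist(),
                 "best_lambda": t.best_lambda, "tolerance_lambda": t.tolerance_lambda}
                for t in (self.pooled.tunings or [])
            ],
        }

    # -- plots ---------------------------------------------------------
    def plot_tuning(self, set_index: int = 0, ax=None):
        """MSE profile over the penalty grid for one imputed set."""
        import matplotlib.pyplot as plt

        t = (self.pooled.tunings or [])[set_index]
        if ax is None:
            _, ax = plt.subplots()
        ax.plot(t.grid, t.mean_boot_mse, marker="o", ms=3)
        ax.axvline(t.best_lambda, ls="--", label="best")
        ax.axvline(t.tolerance_lambda, ls=":", label="tolerance")
        ax.set_xscale("log")
        ax.set_xlabel("penalty")
        ax.set_ylabel("mean bootstrap MSE")
        ax.legend()
        return ax

    def plot_calibration(self, dataset: Dataset | None = None, ax=None):
        """Observed vs predicted with the calibration line and decile means."""
        import matplotlib.pyplot as plt

        ds = dataset if dataset is not None else self.model.imputed.sets[0]
        cal = self.calibration(ds)
        pred = self.predict(ds)
        if ax is None:
            _, ax = plt.subplots()
        ax.scatter(pred, ds.outcome, s=5, alpha=0.3, color="gray")
        lo, hi = float(pred.min()), float(pred.max())
        xs = np.linspace(lo, hi, 50)
        ax.plot(xs, xs, color="gray", lw=1, label="perfect")
        ax.plot(xs, cal.intercept_lp + cal.slope_lp * xs, color="black", label="calibration line")
        ax.scatter(cal.decile_table["mean_predicted"], cal.decile_table["mean_observed"],
                   marker="^", color="black", label="decile means")
        ax.set_xlabel("predicted")
        ax.set_ylabel("observed")
        ax.legend()
        return ax


def _infer_types(values: np.ndarray, mask: np.ndarray) -> list[str]:
    types = []
    for j in range(values.shape[1]):
        obs = values[mask[:, j], j]
        types.append("binary" if obs.size and np.isin(obs, (0.0, 1.0)).all() else "continuous")
    return types
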