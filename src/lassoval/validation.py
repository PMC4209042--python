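"""Internal validation: bootstrap estimation of optimism and shrinkage.

The optimism bootstrap replays the *entire* model-building pipeline (penalty
tuning, per-set fitting, pooling) inside each bootstrap resample, measures
the resampled model on its own bootstrap data (``apparent*``) and on the
original data (``test*``), and takes ``optimism* = apparent* - test*``; the
optimism-corrected performance is the original apparent performance minus
the mean of the B optimism values.  With MSE the optimism values are
typically negative, so the correction increases the MSE estimate.  The
uniform shrinkage factor ``s`` is the mean over bootstraps of the slope from
regressing the original outcome on the bootstrap model's linear predictor.

With multiply imputed data there are four ways to resample:

1. one shared row-index vector applied to every imputed set (bootstrap
   samples differ only by their imputed values);
2. an independent index vector per imputed set;
3. resample a single chosen imputed set, exactly as in the no-missing-data
   procedure;
4. resample the *incomplete* data and re-impute M times inside every
   bootstrap run, so the imputation step itself is validated.

Seed layout (stable API, relied on for reproducibility): the seed opens a
``SeedSequence`` whose first two children serve the original fit and the
bootstrap loop; the loop child spawns one stream per bootstrap, and each
bootstrap stream spawns, in order, the index draw, the model-building seed,
and (approach 4) the re-imputation seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import Dataset, ImputedSets, as_imputed_sets
from .impute import impute
from .lasso import (DEFAULT_N_BOOT, DEFAULT_N_LAMBDA, DEFAULT_TOLERANCE,
                    fit_pooled)
from .performance import apparent_performance, pooled_calibration_slope

logger = logging.getLogger(__name__)

APPROACHES = (1, 2, 3, 4)
DEFAULT_B = 100


@dataclass
class ValidationReport:
    """Bookkeeping of one optimism-bootstrap run for one model mode."""

    approach: int
    mode: str
    n_boot: int
    apparent: float
    records: pd.DataFrame            # columns: apparent, test, optimism, lp_slope
    settings: dict = field(default_factory=dict)

    @property
    def mean_optimism(self) -> float:
        return float(self.records["optimism"].mean())

    @property
    def corrected_performance(self) -> float:
        return corrected_performance(self.apparent, self.records["optimism"].to_numpy())

    @property
    def shrinkage_s(self) -> float:
        return shrinkage_factor(self)

    def to_dict(self) -> dict:
        return {
            "approach": self.approach,
            "mode": self.mode,
            "n_boot": self.n_boot,
            "apparent": self.apparent,
            "mean_optimism": self.mean_optimism,
            "corrected_performance": self.corrected_performance,
            "shrinkage_s": self.shrinkage_s,
            "settings": self.settings,
            "records": self.records.to_dict(orient="list"),
        }


def corrected_performance(apparent: float, optimisms) -> float:
    """Optimism-corrected performance: ``apparent - mean(optimisms)``."""
    optimisms = np.asarray(optimisms, dtype=float)
    if optimisms.size < 1:
        raise ValueError("need at least one optimism value")
    return float(apparent - optimisms.mean())


def shrinkage_factor(report: ValidationReport) -> float:
    """Mean of the per-bootstrap calibration slopes (non-finite excluded)."""
    slopes = report.records["lp_slope"].to_numpy(dtype=float)
    finite = np.isfinite(slopes)
    if not finite.any():
        raise ValueError("no finite linear-predictor slopes recorded")
    if not finite.all():
        logger.warning("excluding %d non-finite bootstrap slopes", (~finite).sum())
    return float(slopes[finite].mean())


def _default_fit_fn(n_lambda, n_boot_tune, tolerance_fraction, modes):
    def fit(sets: ImputedSets, seed):
        return fit_pooled(sets, modes, n_lambda=n_lambda, n_boot=n_boot_tune,
                          seed=seed, tolerance_fraction=tolerance_fraction)
    return fit


def bootstrap_optimism(
    source,
    approach: int,
    B: int = DEFAULT_B,
    mode="best",
    n_lambda: int = DEFAULT_N_LAMBDA,
    n_boot_tune: int = DEFAULT_N_BOOT,
    tolerance_fraction: float = DEFAULT_TOLERANCE,
    m: int | None = None,
    impute_kwargs: dict | None = None,
    set_index: int = 0,
    original_sets: ImputedSets | None = None,
    apparent=None,
    seed=None,
    fit_fn=None,
):
    """Run the optimism bootstrap under one of the four MI-handling approaches.

    ``source`` is an :class:`ImputedSets` (or complete Dataset) for
    approaches 1-3 and the *incomplete* Dataset for approach 4; approach 4
    additionally needs ``original_sets``, the imputations of the original
    data on which apparent/test performance is measured (if omitted they are
    generated from a dedicated substream).

    ``mode`` may be ``"best"``, ``"tolerance"`` or a sequence; with a
    sequence a dict of reports sharing one bootstrap pass is returned (the
    two modes share every tuning profile, so this halves the cost).
    ``apparent`` optionally supplies the precomputed original apparent
    performance (float, or dict by mode) and skips the original refit.
    ``fit_fn(sets, seed) -> model`` (or dict by mode) replaces the whole
    model-building step; used to validate arbitrary builders.
    """
    if approach not in APPROACHES:
        raise ValueError(f"approach must be one of {APPROACHES}")
    if B < 1:
        raise ValueError("B must be >= 1")
    modes = (mode,) if isinstance(mode, str) else tuple(mode)

    impute_kwargs = dict(impute_kwargs or {})
    if approach == 4:
        if not isinstance(source, Dataset):
            raise TypeError("approach 4 resamples the incomplete Dataset")
        incomplete = source
        if m is None:
            m = original_sets.m if original_sets is not None else 10
    else:
        sets = as_imputed_sets(source)
        if approach == 3:
            if not 0 <= set_index < sets.m:
                raise ValueError("set_index out of range")
            eval_sets = ImputedSets([sets.sets[set_index]], sets.source_mask, sets.seed)
        else:
            eval_sets = sets

    root = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    s_orig, s_boot = root.spawn(2)

    if fit_fn is None:
        fit_fn = _default_fit_fn(n_lambda, n_boot_tune, tolerance_fraction, modes)

    if approach == 4 and original_sets is None:
        original_sets = impute(incomplete, m=m, seed=s_orig.spawn(1)[0], **impute_kwargs)
    if approach == 4:
        eval_sets = original_sets
        n_rows = incomplete.n
    else:
        n_rows = eval_sets.sets[0].n

    # original apparent performance on the same sets test* is measured on
    # (all original imputed sets; approach 3 validates its single chosen set)
    apparent_sets = eval_sets
    if apparent is None:
        orig_models = fit_fn(apparent_sets, s_orig)
        if not isinstance(orig_models, dict):
            orig_models = {md: orig_models for md in modes}
        apparent_by_mode = {
            md: apparent_performance(orig_models[md], apparent_sets) for md in modes
        }
    elif isinstance(apparent, dict):
        apparent_by_mode = {md: float(apparent[md]) for md in modes}
    else:
        apparent_by_mode = {md: float(apparent) for md in modes}

    rows = {md: [] for md in modes}
    for stream in s_boot.spawn(B):
        s_idx, s_fit, s_imp = stream.spawn(3)
        rng = np.random.default_rng(s_idx)
        if approach == 1 or approach == 3:
            idx = rng.integers(0, n_rows, size=n_rows)
            boot_sets = eval_sets.subset(idx)
        elif approach == 2:
            idx = [rng.integers(0, n_rows, size=n_rows) for _ in range(eval_sets.m)]
            boot_sets = eval_sets.subset(idx)
        else:  # approach 4: resample incomplete rows, then re-impute
            idx = rng.integers(0, n_rows, size=n_rows)
            boot_incomplete = Dataset(
                incomplete.values[idx], incomplete.mask[idx],
                list(incomplete.columns), list(incomplete.var_types),
            )
            boot_sets = impute(boot_incomplete, m=m, seed=s_imp, **impute_kwargs)

        models = fit_fn(boot_sets, s_fit)
        if not isinstance(models, dict):
            models = {md: models for md in modes}
        for md in modes:
            app_star = apparent_performance(models[md], boot_sets)
            test_star = apparent_performance(models[md], eval_sets)
            slope_star = pooled_calibration_slope(models[md], eval_sets)
            rows[md].append((app_star, test_star, app_star - test_star, slope_star))

    settings = {
        "mode": None, "n_lambda": n_lambda, "n_boot_tune": n_boot_tune,
        "tolerance_fraction": tolerance_fraction, "m": m, "set_index": set_index,
        "B": B,
    }
    reports = {}
    for md in modes:
        rec = pd.DataFrame(rows[md], columns=["apparent", "test", "optimism", "lp_slope"])
        st = dict(settings, mode=md)
        reports[md] = ValidationReport(approach, md, B, apparent_by_mode[md], rec, st)
    return reports[modes[0]] if isinstance(mode, str) else reports
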