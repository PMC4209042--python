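"""Monte-Carlo study comparing internal and external optimism estimates.

Each replicate draws a training cohort, builds the best- and tolerance-
penalty models, and measures

* ``mse_apparent`` — averaged MSE of the final model on its training
  (imputed) data;
* ``mse_external`` — MSE on a freshly simulated complete cohort of the same
  size (the gold standard);
* ``optimism_external = mse_apparent - mse_external``;
* ``optimism_internal`` — the bootstrap estimate, in the no-missing (NM)
  setting via the plain optimism bootstrap, in the with-missing (WM) setting
  under each requested MI-handling approach;

plus the calibration slope on the training data, the shrinkage factor per
approach, and per-covariate selection counts across the imputed sets.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .data import ImputedSets
from .impute import impute
from .lasso import MODES, fit_pooled
from .performance import apparent_performance, mse, pooled_calibration_slope
from .simulate import RELEVANT_COVARIATES, SimConfig, apply_mcar, simulate_complete
from .validation import bootstrap_optimism


@dataclass
class StudyOptions:
    """Problem sizes of one simulation run (defaults mirror the full design)."""

    n_lambda: int = 40
    n_boot_tune: int = 100
    B: int = 100
    m: int = 10
    n_cycles: int = 5
    pmm_donors: int = 5
    tolerance_fraction: float = 0.03
    approaches: tuple[int, ...] = (1, 2, 3, 4)
    validate: bool = True
    external_n: int | None = None
    modes: tuple[str, ...] = MODES

    def desk_scale(self) -> "StudyOptions":
        """Reduced preset for desk-scale runs (recorded in output metadata)."""
        return replace(self, n_boot_tune=30, B=30, n_lambda=20, m=5)

    def to_dict(self) -> dict:
        return {k: (list(v) if isinstance(v, tuple) else v) for k, v in self.__dict__.items()}


def run_replicate(
    config: SimConfig,
    setting: str,
    seed=None,
    options: StudyOptions | None = None,
    replicate_id: int = 0,
) -> list[dict]:
    """One simulation replicate; returns one record dict per model mode.

    ``setting`` is ``"nm"`` (fit on the complete draw) or ``"wm"`` (apply
    MCAR missingness, impute M times, pool).  The WM replicate with all
    missingness probabilities zero reproduces the NM record under the same
    seed, since imputing a complete dataset yields identical copies.
    """
    setting = setting.lower()
    if setting not in ("nm", "wm"):
        raise ValueError("setting must be 'nm' or 'wm'")
    opts = options or StudyOptions()
    root = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    s_data, s_mcar, s_imp, s_fit, s_ext, s_val = root.spawn(6)
    s_val_children = s_val.spawn(4)  # indexed by approach - 1; NM uses [0]

    train = simulate_complete(config, seed=s_data)
    ext_cfg = replace(config, n_obs=opts.external_n or config.n_obs,
                      miss_probs={}, seed=None)
    external = simulate_complete(ext_cfg, seed=s_ext)

    if setting == "wm":
        incomplete = apply_mcar(train, config.miss_probs, seed=s_mcar)
        sets = impute(incomplete, m=opts.m, n_cycles=opts.n_cycles,
                      pmm_donors=opts.pmm_donors, seed=s_imp)
    else:
        sets = ImputedSets([train], train.mask.copy())

    pooled = fit_pooled(sets, opts.modes, n_lambda=opts.n_lambda,
                        n_boot=opts.n_boot_tune, seed=s_fit,
                        tolerance_fraction=opts.tolerance_fraction)
    apparent = {md: apparent_performance(pooled[md], sets) for md in opts.modes}

    reports: dict[int, dict] = {}
    if opts.validate:
        common = dict(mode=opts.modes, n_lambda=opts.n_lambda,
                      n_boot_tune=opts.n_boot_tune,
                      tolerance_fraction=opts.tolerance_fraction,
                      apparent=apparent)
        if setting == "nm":
            reports[0] = bootstrap_optimism(sets, 1, B=opts.B,
                                            seed=s_val_children[0], **common)
        else:
            for a in opts.approaches:
                src = incomplete if a == 4 else sets
                reports[a] = bootstrap_optimism(
                    src, a, B=opts.B, m=opts.m,
                    impute_kwargs=dict(n_cycles=opts.n_cycles, pmm_donors=opts.pmm_donors),
                    original_sets=sets if a == 4 else None,
                    seed=s_val_children[a - 1], **common,
                )

    rows = []
    for md in opts.modes:
        model = pooled[md]
        row = {
            "replicate": replicate_id,
            "setting": setting,
            "mode": md,
            "n": config.n_obs,
            "m": sets.m,
            "mse_apparent": apparent[md],
            "mse_external": mse(model, external),
            "lp_slope": pooled_calibration_slope(model, sets),
        }
        row["optimism_external"] = row["mse_apparent"] - row["mse_external"]
        if opts.validate:
            if setting == "nm":
                rep = reports[0][md]
                row["optimism_internal"] = rep.mean_optimism
                row["shrinkage"] = rep.shrinkage_s
                row["mse_corrected"] = rep.corrected_performance
            else:
                for a in opts.approaches:
                    rep = reports[a][md]
                    row[f"optimism_appr{a}"] = rep.mean_optimism
                    row[f"shrinkage_appr{a}"] = rep.shrinkage_s
                    row[f"mse_corrected_appr{a}"] = rep.corrected_performance
        for j, count in enumerate(model.selection_counts, start=1):
            row[f"sel_x{j}"] = int(count)
        rows.append(row)
    return rows


def run_study(
    config: SimConfig,
    setting: str,
    n_reps: int,
    seed=None,
    options: StudyOptions | None = None,
    progress=None,
) -> pd.DataFrame:
    """Run ``n_reps`` independent replicates; one row per (replicate, mode).

    Replicates get independent seed substreams keyed by replicate id, so the
    result is invariant to execution order.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    root = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rows = []
    for rid, child in enumerate(root.spawn(n_reps)):
        rows.extend(run_replicate(config, setting, child, options, replicate_id=rid))
        if progress is not None:
            progress(rid + 1, n_reps)
    return pd.DataFrame(rows)


def selection_frequencies(records: pd.DataFrame, wm_rule: float = 0.5):
    """Per-covariate selection frequencies and correct-model rates.

    A covariate counts as selected when retained (nonzero) in at least
    ``ceil(wm_rule * M)`` of the M imputed sets (with M = 1 this is simply a
    nonzero coefficient).  The correct-model rate is the fraction of
    replicates in which all truly relevant covariates are selected
    simultaneously; the one-off rate is the fraction missing exactly one of
    them.  Returns ``(frequencies, rates)`` DataFrames, both in percent,
    grouped by (setting, mode).
    """
    if records.empty:
        raise ValueError("no records")
    sel_cols = sorted(
        (c for c in records.columns if c.startswith("sel_x")),
        key=lambda c: int(c[5:]),
    )
    relevant = [f"sel_x{j}" for j in RELEVANT_COVARIATES]
    freq_rows, rate_rows = [], []
    for (setting, md), grp in records.groupby(["setting", "mode"], sort=False):
        need = np.maximum(1, np.ceil(wm_rule * grp["m"].to_numpy()).astype(int))
        selected = grp[sel_cols].to_numpy() >= need[:, None]
        freq = pd.Series(100.0 * selected.mean(axis=0), index=sel_cols)
        freq_rows.append({"setting": setting, "mode": md,
                          **{c.replace("sel_", ""): v for c, v in freq.items()}})
        rel_idx = [sel_cols.index(c) for c in relevant]
        n_rel = selected[:, rel_idx].sum(axis=1)
        rate_rows.append({
            "setting": setting, "mode": md,
            "correct_model_pct": 100.0 * float(np.mean(n_rel == len(relevant))),
            "one_off_pct": 100.0 * float(np.mean(n_rel == len(relevant) - 1)),
        })
    return pd.DataFrame(freq_rows), pd.DataFrame(rate_rows)


def summarize(records: pd.DataFrame) -> pd.DataFrame:
    """Mean, 2.5th and 97.5th percentile of every numeric quantity, grouped
    by (setting, mode).  Percentiles interpolate linearly between order
    statistics."""
    if records.empty:
        raise ValueError("no records")
    drop = {"replicate", "setting", "mode"}
    num_cols = [c for c in records.columns
                if c not in drop and pd.api.types.is_numeric_dtype(records[c])]
    rows = []
    for (setting, md), grp in records.groupby(["setting", "mode"], sort=False):
        for c in num_cols:
            vals = grp[c].dropna().to_numpy(dtype=float)
            if vals.size == 0:
                continue
            rows.append({
                "setting": setting, "mode": md, "quantity": c,
                "mean": float(vals.mean()),
                "p2.5": float(np.percentile(vals, 2.5)),
                "p97.5": float(np.percentile(vals, 97.5)),
                "n_reps": int(vals.size),
            })
    return pd.DataFrame(rows)
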