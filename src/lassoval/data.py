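"""Tabular containers and CSV round-tripping.

A :class:`Dataset` is a rectangular table of covariates plus a single
continuous outcome (always the last column), together with a boolean
observation mask and a per-column variable type (``"continuous"`` or
``"binary"``).  Missing cells are represented by ``mask == False``; the
underlying ``values`` entry for a masked cell may still carry the true
(pre-deletion) value when the dataset was produced by the simulator, which
lets tests compare imputations against the truth.  On disk, masked cells are
written as empty fields (NA).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

CONTINUOUS = "continuous"
BINARY = "binary"


class SchemaError(ValueError):
    """Raised when a table violates its declared column schema."""


@dataclass
class Dataset:
    values: np.ndarray              # (n, p+1) float64, outcome last
    mask: np.ndarray                # (n, p+1) bool, True = observed
    columns: list[str]
    var_types: list[str]            # per column, outcome included

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != self.mask.shape:
            raise SchemaError("values and mask shapes differ")
        if self.values.shape[1] != len(self.columns) or len(self.columns) != len(self.var_types):
            raise SchemaError("column metadata length mismatch")
        for j, t in enumerate(self.var_types):
            if t not in (CONTINUOUS, BINARY):
                raise SchemaError(f"unknown var_type {t!r} for column {self.columns[j]}")
            if t == BINARY:
                obs = self.values[self.mask[:, j], j]
                if obs.size and not np.isin(obs, (0.0, 1.0)).all():
                    raise SchemaError(
                        f"binary column {self.columns[j]!r} contains values outside {{0,1}}"
                    )

    # -- shape helpers -------------------------------------------------
    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def n_cov(self) -> int:
        return self.values.shape[1] - 1

    @property
    def covariates(self) -> np.ndarray:
        return self.values[:, :-1]

    @property
    def outcome(self) -> np.ndarray:
        return self.values[:, -1]

    @property
    def is_complete(self) -> bool:
        return bool(self.mask.all())

    def copy(self) -> "Dataset":
        return Dataset(self.values.copy(), self.mask.copy(), list(self.columns), list(self.var_types))

    def to_frame(self) -> pd.DataFrame:
        """DataFrame view with NaN at unobserved cells."""
        vals = self.values.copy()
        vals[~self.mask] = np.nan
        return pd.DataFrame(vals, columns=self.columns)

    def require_complete(self, what: str = "operation") -> None:
        if not self.is_complete:
            raise SchemaError(f"{what} requires a dataset without missing cells")


def write_dataset(dataset: Dataset, path: str | Path, config: dict | None = None) -> None:
    """Write ``dataset`` to CSV (masked cells as empty fields) plus a sidecar
    ``<stem>.types.json`` recording column types and, optionally, the
    generating configuration."""
    path = Path(path)
    # %.17g guarantees binary round-trip of float64 through text
    dataset.to_frame().to_csv(path, index=False, na_rep="", float_format="%.17g")
    sidecar = {"columns": dataset.columns, "var_types": dataset.var_types}
    if config is not None:
        sidecar["config"] = config
    path.with_suffix(".types.json").write_text(json.dumps(sidecar, indent=1))


def read_dataset(path: str | Path, types_path: str | Path | None = None) -> Dataset:
    """Read a CSV with header; empty/NA cells become unobserved.

    Column types come from ``types_path`` (or the ``<stem>.types.json``
    sidecar if present); otherwise a column is tagged binary when all its
    observed values lie in {0, 1}.
    """
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    values = df.to_numpy(dtype=float)
    mask = ~np.isnan(values)
    columns = list(df.columns)

    if types_path is None:
        sidecar = path.with_suffix(".types.json")
        types_path = sidecar if sidecar.exists() else None
    if types_path is not None:
        meta = json.loads(Path(types_path).read_text())
        var_types = list(meta["var_types"])
        if meta.get("columns") not in (None, columns):
            raise SchemaError("types file columns do not match CSV header")
    else:
        var_types = []
        for j in range(values.shape[1]):
            obs = values[mask[:, j], j]
            var_types.append(BINARY if obs.size and np.isin(obs, (0.0, 1.0)).all() else CONTINUOUS)
    return Dataset(values, mask, columns, var_types)


@dataclass
class ImputedSets:
    """M completed copies of a source dataset sharing rows and schema."""

    sets: list[Dataset]
    source_mask: np.ndarray
    seed: int | None = None
    m: int = field(init=False)

    def __post_init__(self) -> None:
        if not self.sets:
            raise SchemaError("ImputedSets needs at least one completed dataset")
        self.m = len(self.sets)
        ref = self.sets[0]
        for ds in self.sets:
            if ds.values.shape != ref.values.shape or ds.columns != ref.columns:
                raise SchemaError("imputed sets do not share shape/schema")
            if not ds.is_complete:
                raise SchemaError("imputed sets must be complete")

    def __iter__(self):
        return iter(self.sets)

    def __len__(self) -> int:
        return self.m

    @property
    def columns(self) -> list[str]:
        return self.sets[0].columns

    def subset(self, idx: np.ndarray | list[np.ndarray]) -> "ImputedSets":
        """Row-resample every set.  ``idx`` is either one index vector applied
        to all sets, or one vector per set."""
        if isinstance(idx, np.ndarray) and idx.ndim == 1:
            idx = [idx] * self.m
        sets = [
            Dataset(ds.values[ix], ds.mask[ix], list(ds.columns), list(ds.var_types))
            for ds, ix in zip(self.sets, idx)
        ]
        return ImputedSets(sets, self.source_mask[idx[0]], self.seed)


def as_imputed_sets(data) -> ImputedSets:
    """Wrap a complete Dataset as a single-set ImputedSets; pass through."""
    if isinstance(data, ImputedSets):
        return data
    if isinstance(data, Dataset):
        data.require_complete("analysis")
        return ImputedSets([data], data.mask.copy())
    raise TypeError(f"expected Dataset or ImputedSets, got {type(data).__name__}")
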