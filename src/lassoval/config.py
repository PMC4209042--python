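"""Run configuration: defaults, file loading, flag overrides."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, fields
from pathlib import Path

import yaml


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    """Numeric settings shared by the CLI subcommands.

    Defaults are the full-scale analysis settings: a 40-value penalty grid,
    100 tuning and 100 validation bootstraps, 10 imputations, and a 3%
    tolerance band for the parsimonious model.
    """

    n_lambda: int = 40
    tolerance_fraction: float = 0.03
    n_boot_tune: int = 100
    n_boot_validate: int = 100
    m: int = 10
    n_cycles: int = 5
    pmm_donors: int = 5
    seed: int | None = None
    verbose: bool = False

    def __post_init__(self) -> None:
        if self.tolerance_fraction < 0:
            raise ConfigError("tolerance_fraction must be >= 0")
        for name in ("n_lambda", "n_boot_tune", "n_boot_validate", "m", "n_cycles", "pmm_donors"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be >= 1")

    def to_dict(self) -> dict:
        return asdict(self)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))


def load_config(path: str | Path | None = None, **overrides) -> RunConfig:
    """Build a RunConfig from an optional JSON/YAML file plus flag overrides.

    Flags (non-None overrides) take precedence over file values; unknown
    keys in the file are an error listing the offenders.
    """
    values: dict = {}
    if path is not None:
        path = Path(path)
        text = path.read_text()
        if path.suffix.lower() in (".yaml", ".yml"):
            loaded = yaml.safe_load(text) or {}
        else:
            loaded = json.loads(text)
        if not isinstance(loaded, dict):
            raise ConfigError(f"config file {path} must hold a mapping")
        known = {f.name for f in fields(RunConfig)}
        unknown = sorted(set(loaded) - known)
        if unknown:
            raise ConfigError(f"unknown config keys: {', '.join(unknown)}")
        values.update(loaded)
    values.update({k: v for k, v in overrides.items() if v is not None})
    return RunConfig(**values)
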