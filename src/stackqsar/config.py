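"""Run configuration: YAML schema, validation and resolution."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any, Mapping

import yaml

from .base import ALGORITHMS
from .curation import LabelThresholds
from .descriptors import REGISTRY
from .selection import SelectionGrid


class ConfigError(ValueError):
    """Invalid run configuration."""


@dataclass
class RunConfig:
    """Validated configuration for a full stacked-ensemble run."""

    compound_table: str | None = None
    dialect: str = "generic_csv"
    fingerprint_imports: dict[str, str] = field(default_factory=dict)
    out_dir: str = "stackqsar_out"
    target_name: str = ""

    active_max_nM: float = 1000.0
    inactive_min_nM: float = 10000.0
    train_fraction: float = 0.8

    descriptors: list[str] | None = None
    algorithms: list[str] = field(default_factory=lambda: list(ALGORITHMS))
    grids: dict[str, dict[str, list]] = field(default_factory=dict)
    k: int = 10
    selection_grid: dict[str, int] = field(
        default_factory=lambda: {"m_start": 5, "m_end": 70, "s": 5}
    )
    meta_grid: dict[str, list] | None = None
    pf_mode: str = "concat"
    pf_tuning: str = "shared"
    cv_scoring: str = "pooled"
    seed: int = 0

    def __post_init__(self) -> None:
        for a in self.algorithms:
            if a not in ALGORITHMS:
                raise ConfigError(f"unknown algorithm {a!r}")
        if self.descriptors is not None:
            for d in self.descriptors:
                if d not in REGISTRY:
                    raise ConfigError(f"unknown descriptor family {d!r}")
        for d in self.fingerprint_imports:
            if d not in REGISTRY:
                raise ConfigError(f"unknown descriptor family in imports: {d!r}")
        if self.pf_mode not in ("concat", "average"):
            raise ConfigError(f"pf_mode must be concat|average, got {self.pf_mode!r}")
        if self.pf_tuning not in ("shared", "per_fold"):
            raise ConfigError(f"pf_tuning must be shared|per_fold, got {self.pf_tuning!r}")
        if self.cv_scoring not in ("pooled", "macro"):
            raise ConfigError(f"cv_scoring must be pooled|macro, got {self.cv_scoring!r}")
        self.thresholds()  # validates ordering
        self.selection()

    def thresholds(self) -> LabelThresholds:
        return LabelThresholds(self.active_max_nM, self.inactive_min_nM)

    def selection(self) -> SelectionGrid:
        try:
            return SelectionGrid(**self.selection_grid)
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"invalid selection_grid: {exc}") from exc

    def estimator_params(self) -> dict[str, Any]:
        return {
            "algorithms": self.algorithms,
            "descriptors": self.descriptors,
            "grids": self.grids or None,
            "k": self.k,
            "selection_grid": self.selection(),
            "meta_grid": self.meta_grid,
            "pf_mode": self.pf_mode,
            "pf_tuning": self.pf_tuning,
            "random_state": self.seed,
        }

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))


def load_config(path: str | Path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, Mapping):
        raise ConfigError(f"config root must be a mapping, got {type(raw).__name__}")
    known = {f for f in RunConfig.__dataclass_fields__}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    try:
        return RunConfig(**raw)
    except TypeError as exc:
        raise ConfigError(str(exc)) from exc
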