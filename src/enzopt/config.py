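"""Run configuration: YAML/JSON loading with strict schemas, and manifests.

A run configuration is a nested mapping with three sections (``ga``,
``strategy``, ``models``) plus a few global keys.  Unknown keys are
rejected with a path-to-field message, defaults match the published
protocol (population 500, 30 generations, retention 0.8, 3 candidates per
masked position, 5 CV folds, 100 ps snapshots), and a loaded config
round-trips through :func:`echo_config` unchanged.

Every CLI run writes a manifest (config echo, seed, package version, input
checksums) so a published run can be replayed bit-for-bit.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import yaml

from .ga_engine import GAConfig
from .mutation_strategies import StrategyConfig


@dataclass(frozen=True)
class ModelDefaults:
    """Default hyperparameters for the trainable fitness models."""

    folds: int = 5
    feasibility_trees: int = 100
    kcat_log_base: float = 10.0
    snapshot_spacing_ps: float = 100.0

    def __post_init__(self) -> None:
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if self.feasibility_trees < 1:
            raise ValueError("feasibility_trees must be >= 1")
        if self.kcat_log_base <= 1:
            raise ValueError("kcat_log_base must be > 1")
        if self.snapshot_spacing_ps <= 0:
            raise ValueError("snapshot_spacing_ps must be positive")


@dataclass(frozen=True)
class RunConfig:
    """Fully resolved configuration for one CLI run."""

    ga: GAConfig = field(default_factory=GAConfig)
    models: ModelDefaults = field(default_factory=ModelDefaults)
    seed: int = 0
    output_dir: str = "."
    log_level: str = "INFO"

    def to_dict(self) -> dict[str, Any]:
        d = asdict(self)
        strategy = d["ga"].pop("strategy_config")
        d["strategy"] = strategy
        return d


_GA_KEYS = {
    "population_size",
    "generations",
    "retain_fraction",
    "crossover_rate",
    "crossover_kind",
    "seed",
    "stop_on_score",
}
_STRATEGY_KEYS = {
    "strategy",
    "max_mutations",
    "editable_region",
    "candidates_per_position",
    "selection_mode",
    "seed",
    "max_retries",
}
_MODEL_KEYS = {"folds", "feasibility_trees", "kcat_log_base", "snapshot_spacing_ps"}
_TOP_KEYS = {"ga", "strategy", "models", "seed", "output_dir", "log_level"}


class ConfigError(ValueError):
    """Schema violation in a run configuration file."""


def _check_keys(section: dict, allowed: set[str], path: str) -> None:
    unknown = set(section) - allowed
    if unknown:
        raise ConfigError(
            f"unknown key(s) {sorted(unknown)} at {path or '<top level>'}; "
            f"allowed: {sorted(allowed)}"
        )


def config_from_dict(data: dict[str, Any] | None) -> RunConfig:
    """Build a :class:`RunConfig` from a nested mapping, filling defaults."""
    data = dict(data or {})
    _check_keys(data, _TOP_KEYS, "")
    ga_section = dict(data.get("ga") or {})
    strategy_section = dict(data.get("strategy") or {})
    models_section = dict(data.get("models") or {})
    _check_keys(ga_section, _GA_KEYS, "ga")
    _check_keys(strategy_section, _STRATEGY_KEYS, "strategy")
    _check_keys(models_section, _MODEL_KEYS, "models")
    if "editable_region" in strategy_section and strategy_section["editable_region"] is not None:
        strategy_section["editable_region"] = tuple(strategy_section["editable_region"])
    try:
        strategy = StrategyConfig(**strategy_section)
        ga = GAConfig(strategy_config=strategy, **ga_section)
        models = ModelDefaults(**models_section)
    except (TypeError, ValueError) as exc:
        raise ConfigError(str(exc)) from exc
    return RunConfig(
        ga=ga,
        models=models,
        seed=int(data.get("seed", 0)),
        output_dir=str(data.get("output_dir", ".")),
        log_level=str(data.get("log_level", "INFO")),
    )


def load_config(path: str | Path) -> RunConfig:
    """Load a YAML or JSON run configuration."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)  # YAML is a superset of JSON
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError(f"config root must be a mapping, got {type(data).__name__}")
    return config_from_dict(data)


def echo_config(cfg: RunConfig, path: str | Path) -> None:
    """Write the resolved configuration back out as JSON (the config echo)."""
    Path(path).write_text(json.dumps(cfg.to_dict(), indent=2, sort_keys=True) + "\n")


def file_checksum(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_manifest(
    path: str | Path,
    cfg: RunConfig | None,
    seed: int,
    inputs: dict[str, str | Path] | None = None,
    extra: dict[str, Any] | None = None,
) -> None:
    """Write a replayable run manifest: config echo, seed, version, checksums."""
    from . import __version__

    manifest: dict[str, Any] = {
        "package_version": __version__,
        "seed": seed,
        "config": cfg.to_dict() if cfg is not None else None,
        "input_checksums": {
            name: file_checksum(p) for name, p in (inputs or {}).items()
        },
    }
    if extra:
        manifest.update(extra)
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
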