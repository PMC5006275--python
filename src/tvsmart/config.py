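"""Scenario configuration: YAML serialization, validation, shipped presets.

A scenario file has four blocks::

    design:       # DesignSpec fields (all required)
    params:       # GenParams fields (all required)
    replication:  # R, n, seed, estimators, mechanism   (optional, defaulted)
    evaluation:   # level, direction, nodes, cost block (optional, defaulted)

Unknown keys anywhere are rejected with their field path.  Presets named
after the simulation scenarios they encode ship with the package and can be
referenced by name wherever a scenario path is accepted.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml

from .design import DesignSpec
from .simulate import GenParams

__all__ = [
    "ConfigError",
    "ReplicationConfig",
    "EvaluationConfig",
    "ScenarioConfig",
    "load_scenario",
    "save_scenario",
    "list_presets",
]


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class ReplicationConfig:
    R: int = 500
    n: int = 1000
    seed: int = 0
    estimators: tuple[str, ...] = ("tvmem", "joint")
    mechanism: str = "weibull"

    def __post_init__(self) -> None:
        if self.R < 1 or self.n < 1:
            raise ConfigError("replication.R and replication.n must be >= 1")
        bad = set(self.estimators) - {"tvmem", "joint"}
        if bad:
            raise ConfigError(f"replication.estimators: unknown estimator(s) {sorted(bad)}")
        if self.mechanism not in ("weibull", "boundary"):
            raise ConfigError("replication.mechanism must be 'weibull' or 'boundary'")


@dataclass(frozen=True)
class EvaluationConfig:
    level: float = 0.95
    direction: str = "maximize"
    nodes: int = 15
    oracle_n: int = 100_000
    c1: float = 2.0
    c2: float = 1.0
    c1_grid: tuple[float, ...] = (0.5, 1.0, 1.5, 2.0)
    c2_grid: tuple[float, ...] = (0.5, 1.0, 1.5, 2.0)

    def __post_init__(self) -> None:
        if not 0.0 < self.level < 1.0:
            raise ConfigError("evaluation.level must be in (0, 1)")
        if self.direction not in ("maximize", "minimize"):
            raise ConfigError("evaluation.direction must be 'maximize' or 'minimize'")
        if self.nodes < 5:
            raise ConfigError("evaluation.nodes must be >= 5")


@dataclass(frozen=True)
class ScenarioConfig:
    design: DesignSpec
    params: GenParams
    replication: ReplicationConfig = field(default_factory=ReplicationConfig)
    evaluation: EvaluationConfig = field(default_factory=EvaluationConfig)


_BLOCKS = {
    "design": (DesignSpec, True),
    "params": (GenParams, True),
    "replication": (ReplicationConfig, False),
    "evaluation": (EvaluationConfig, False),
}


def _build(cls, block: dict, path: str, require_all: bool):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(block) - names
    if unknown:
        raise ConfigError(f"{path}: unknown key(s) {sorted(unknown)}")
    if require_all:
        missing = names - set(block)
        if missing:
            raise ConfigError(f"{path}: missing required field(s) {sorted(missing)}")
    kwargs = dict(block)
    for f in dataclasses.fields(cls):
        if f.name in kwargs and isinstance(kwargs[f.name], list):
            kwargs[f.name] = tuple(kwargs[f.name])
    try:
        return cls(**kwargs)
    except (ValueError, TypeError) as exc:
        raise ConfigError(f"{path}: {exc}") from exc


def _preset_path(name: str):
    ref = resources.files("tvsmart").joinpath("presets", f"{name}.yaml")
    return ref if ref.is_file() else None


def list_presets() -> list[str]:
    root = resources.files("tvsmart").joinpath("presets")
    return sorted(p.name[:-5] for p in root.iterdir() if p.name.endswith(".yaml"))


def load_scenario(path) -> ScenarioConfig:
    """Load and validate a scenario file (or shipped preset name)."""
    src = Path(path)
    if not src.exists():
        ref = _preset_path(str(path))
        if ref is None:
            raise ConfigError(
                f"{path!r} is neither a file nor a preset; presets: {list_presets()}"
            )
        text = ref.read_text()
    else:
        text = src.read_text()
    try:
        raw = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ConfigError(f"{path}: not valid YAML: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    unknown = set(raw) - set(_BLOCKS)
    if unknown:
        raise ConfigError(f"{path}: unknown block(s) {sorted(unknown)}")
    built = {}
    for name, (cls, required_block) in _BLOCKS.items():
        if name in raw:
            block = raw[name]
            if not isinstance(block, dict):
                raise ConfigError(f"{path}:{name}: must be a mapping")
            built[name] = _build(cls, block, f"{name}", require_all=required_block)
        elif required_block:
            raise ConfigError(f"{path}: missing required block {name!r}")
        else:
            built[name] = cls()
    return ScenarioConfig(**built)


def save_scenario(config: ScenarioConfig, path) -> None:
    """Write a scenario so that :func:`load_scenario` round-trips it."""
    out = {}
    for name in _BLOCKS:
        block = dataclasses.asdict(getattr(config, name))
        out[name] = {
            k: (list(v) if isinstance(v, tuple) else v) for k, v in block.items()
        }
    Path(path).write_text(yaml.safe_dump(out, sort_keys=False))
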