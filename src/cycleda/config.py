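"""YAML run configuration: strict schema, documented defaults, key-path errors.

An empty config file is itself a valid configuration and resolves to the
desk-scale synthetic benchmark. Unknown keys are rejected; constraint
violations are reported with the dotted key path of the offending section.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, asdict

import yaml

from .losses import LossWeights
from .networks import NetShapeConfig
from .synthetic_domains import ClassSpec, DomainSpec, SyntheticConfig, \
    default_benchmark_config
from .trainer import TrainConfig

COMMANDS = ("simulate", "train", "train-baseline", "evaluate", "compare",
            "ablate")


class ConfigError(ValueError):
    """Configuration problem, message prefixed with the dotted key path."""


@dataclass(frozen=True)
class EvalConfig:
    k: int = 3
    seeds: tuple = (0, 1, 2)

    def __post_init__(self):
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if len(self.seeds) < 1:
            raise ValueError("seeds must be non-empty")


@dataclass(frozen=True)
class PathsConfig:
    data: str | None = None
    out: str | None = None


@dataclass(frozen=True)
class RunConfig:
    synthetic: SyntheticConfig = field(
        default_factory=default_benchmark_config)
    net: NetShapeConfig = field(default_factory=NetShapeConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    eval: EvalConfig = field(default_factory=EvalConfig)
    paths: PathsConfig = field(default_factory=PathsConfig)


def _check_keys(data: dict, allowed, path: str):
    unknown = set(data) - set(allowed)
    if unknown:
        raise ConfigError(f"{path or 'config'}: unknown key(s) "
                          f"{sorted(unknown)}; allowed: {sorted(allowed)}")


def _build_flat(cls, data: dict, path: str, special=None):
    """Construct a flat dataclass from a dict over its defaults."""
    special = special or {}
    names = [f.name for f in dataclasses.fields(cls)]
    _check_keys(data, names, path)
    kwargs = {}
    for k, v in data.items():
        if k in special:
            v = special[k](v, f"{path}.{k}")
        if isinstance(v, list):
            v = tuple(v)
        kwargs[k] = v
    try:
        return cls(**kwargs)
    except (ValueError, TypeError) as exc:
        raise ConfigError(f"{path or cls.__name__}: {exc}") from exc


def _build_domain_spec(data, path):
    if isinstance(data, DomainSpec):
        return data
    try:
        return DomainSpec(domain_id=data.get("domain_id", ""),
                          appearance=tuple(data.get("appearance", ())))
    except (ValueError, AttributeError) as exc:
        raise ConfigError(f"{path}: {exc}") from exc


def _build_class_specs(data, path):
    out = []
    for i, c in enumerate(data):
        if isinstance(c, ClassSpec):
            out.append(c)
        else:
            out.append(_build_flat(ClassSpec, c, f"{path}[{i}]"))
    return tuple(out)


def _build_synthetic(data, path="synthetic") -> SyntheticConfig:
    defaults = asdict(default_benchmark_config())
    names = [f.name for f in dataclasses.fields(SyntheticConfig)]
    _check_keys(data, names, path)
    merged = {**defaults, **data}
    merged["source_spec"] = _build_domain_spec(merged["source_spec"],
                                               f"{path}.source_spec")
    merged["target_spec"] = _build_domain_spec(merged["target_spec"],
                                               f"{path}.target_spec")
    merged["class_specs"] = _build_class_specs(merged["class_specs"],
                                               f"{path}.class_specs")
    try:
        return SyntheticConfig(**merged)
    except ValueError as exc:
        raise ConfigError(f"{path}: {exc}") from exc


def _build_train(data, path="train") -> TrainConfig:
    return _build_flat(
        TrainConfig, data, path,
        special={"weights": lambda v, p:
                 v if isinstance(v, LossWeights)
                 else _build_flat(LossWeights, v, p)})


def from_dict(data: dict | None) -> RunConfig:
    data = data or {}
    if not isinstance(data, dict):
        raise ConfigError("config root must be a mapping")
    _check_keys(data, ("synthetic", "net", "train", "eval", "paths"), "")
    return RunConfig(
        synthetic=_build_synthetic(data.get("synthetic", {})),
        net=_build_flat(NetShapeConfig, data.get("net", {}), "net"),
        train=_build_train(data.get("train", {})),
        eval=_build_flat(EvalConfig, data.get("eval", {}), "eval"),
        paths=_build_flat(PathsConfig, data.get("paths", {}), "paths"),
    )


def load_config(path: str) -> RunConfig:
    """Load a YAML config file merged over the documented defaults."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return from_dict(data)


def to_dict(cfg: RunConfig) -> dict:
    d = asdict(cfg)

    def clean(obj):
        if isinstance(obj, dict):
            return {k: clean(v) for k, v in obj.items()}
        if isinstance(obj, tuple):
            return [clean(v) for v in obj]
        return obj

    return clean(d)


def dump_config(cfg: RunConfig, path: str):
    with open(path, "w") as fh:
        yaml.safe_dump(to_dict(cfg), fh, sort_keys=False)
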