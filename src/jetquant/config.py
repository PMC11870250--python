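"""Run configuration: dataclasses, YAML loading, strict key checking."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml


class ConfigError(ValueError):
    """Unknown or invalid configuration key."""


@dataclass
class PreprocessOptions:
    static_threshold_cm_s: float = 5.0
    enable_offset: bool = True
    enable_unwrap: bool = True


@dataclass
class PlaneOptions:
    spacing_mm: float = 2.5
    count: int = 7
    extent_mm: float = 20.0
    pitch_mm: float = 0.5


@dataclass
class IntervalOptions:
    speed_threshold_cm_s: float = 100.0
    override: tuple[int, int] | None = None


@dataclass
class ContourOptions:
    inner_fraction: float = 0.2
    outer_threshold_cm_s: float = 10.0


@dataclass
class TrackingOptions:
    seed_points_world_mm: list | None = None


@dataclass
class QuantifyOptions:
    planes: PlaneOptions = field(default_factory=PlaneOptions)
    interval: IntervalOptions = field(default_factory=IntervalOptions)
    contour: ContourOptions = field(default_factory=ContourOptions)
    tracking: TrackingOptions = field(default_factory=TrackingOptions)
    rho_g_cm3: float = 1.0


@dataclass
class RunConfig:
    """Top-level pipeline configuration.

    ``study_path``/``mask_path`` point at an existing dataset; alternatively
    ``phantom`` holds generator settings and the pipeline synthesises its
    input.  The config is serialised verbatim into every results file.
    """

    study_path: str | None = None
    mask_path: str | None = None
    phantom: dict | None = None
    preprocess: PreprocessOptions = field(default_factory=PreprocessOptions)
    quantify: QuantifyOptions = field(default_factory=QuantifyOptions)
    out_dir: str = "results"
    seed: int = 0
    log_level: str = "INFO"


def _build(cls, data, path="config"):
    """Recursively construct a dataclass from a mapping, rejecting unknown keys."""
    if data is None:
        return cls()
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: expected a mapping, got {type(data).__name__}")
    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(fields)
    if unknown:
        raise ConfigError(f"{path}: unknown key(s) {sorted(unknown)}")
    kwargs = {}
    for name, value in data.items():
        f = fields[name]
        sub = _DATACLASS_FIELDS.get((cls, name))
        if sub is not None:
            kwargs[name] = _build(sub, value, f"{path}.{name}")
        elif name == "override" and value is not None:
            kwargs[name] = tuple(value)
        else:
            kwargs[name] = value
    return cls(**kwargs)


_DATACLASS_FIELDS = {
    (QuantifyOptions, "planes"): PlaneOptions,
    (QuantifyOptions, "interval"): IntervalOptions,
    (QuantifyOptions, "contour"): ContourOptions,
    (QuantifyOptions, "tracking"): TrackingOptions,
    (RunConfig, "preprocess"): PreprocessOptions,
    (RunConfig, "quantify"): QuantifyOptions,
}


def load_config(path: str | Path) -> RunConfig:
    with open(path) as f:
        data = yaml.safe_load(f)
    return _build(RunConfig, data)


def config_from_dict(data: dict | None) -> RunConfig:
    return _build(RunConfig, data)


def config_to_dict(cfg) -> dict:
    return dataclasses.asdict(cfg)


def config_to_yaml(cfg: RunConfig) -> str:
    return yaml.safe_dump(config_to_dict(cfg), sort_keys=True)
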