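"""Pipeline configuration: nested dataclasses with strict YAML loading.

Defaults mirror the reference protocol throughout: 1 kHz sampling, 10-400 Hz
band-pass with 50-Hz notch, 256-ms windows with 50-ms overlap, up to 8 IMFs
with the first 4 selected, a 2-s feature window, 60 trials per gesture with
a 42/18 candidate/test split, the 52-sample assignment schedule, GA capped
at 100 generations with fivefold cross-validated fitness.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, fields, is_dataclass
from pathlib import Path

import yaml

from .classifier import GAConfig
from .emd import DEFAULT_MAX_IMFS, DEFAULT_MAX_SIFT_ITERS, DEFAULT_STOP_SD
from .preprocess import FilterSpec
from .synth import DEFAULT_GRASP_WEIGHTS, SimulationConfig


@dataclass(frozen=True)
class GestureGroupConfig:
    group: str = "grasping"
    names: tuple[str, str, str] = ("fist", "spherical", "cylindrical")
    base_weights: tuple[float, ...] = DEFAULT_GRASP_WEIGHTS
    difficulty_scales: tuple[float, float, float] = (1.0, 1.0, 1.0)


@dataclass(frozen=True)
class EMDConfig:
    stop_sd: float = DEFAULT_STOP_SD
    max_imfs: int = DEFAULT_MAX_IMFS
    max_sift_iters: int = DEFAULT_MAX_SIFT_ITERS


@dataclass(frozen=True)
class FeatureConfig:
    fixed_k: int = 4
    feature_window_samples: int = 2000
    deadband: float = 0.0
    offset: int = 0
    wamp_threshold: float = 0.0


@dataclass(frozen=True)
class SweepConfig:
    interest: str | None = None          # default: first gesture name
    total: int = 52
    steps: tuple | None = None           # custom count-triples; None = reference
    repeats: int = 10
    retune: str = "step"
    candidate_per_gesture: int = 42
    test_per_gesture: int = 18
    uniform_per_gesture: int = 17


@dataclass(frozen=True)
class DistanceConfig:
    ridge_rel: float = 1e-3
    sqrt: bool = False
    repeats: int = 10


@dataclass(frozen=True)
class PipelineConfig:
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    gestures: GestureGroupConfig = field(default_factory=GestureGroupConfig)
    filter: FilterSpec = field(default_factory=FilterSpec)
    emd: EMDConfig = field(default_factory=EMDConfig)
    features: FeatureConfig = field(default_factory=FeatureConfig)
    ga: GAConfig = field(default_factory=GAConfig)
    sweep: SweepConfig = field(default_factory=SweepConfig)
    distance: DistanceConfig = field(default_factory=DistanceConfig)
    master_seed: int = 0


def _coerce(value, typ):
    # tuples arrive from YAML as lists
    if isinstance(value, list):
        return tuple(_coerce(v, None) for v in value)
    return value


def _build(cls, data: dict, path: str = ""):
    if not isinstance(data, dict):
        raise ValueError(f"config section '{path or cls.__name__}' must be a "
                         f"mapping, got {type(data).__name__}")
    known = {f.name: f for f in fields(cls)}
    unknown = set(data) - set(known)
    if unknown:
        raise ValueError(
            f"unknown config key(s) in '{path or 'top level'}': "
            f"{sorted(unknown)}")
    kwargs = {}
    for name, value in data.items():
        f = known[name]
        sub = f.default_factory() if f.default_factory is not dataclasses.MISSING else f.default
        if is_dataclass(sub) and isinstance(value, dict):
            kwargs[name] = _build(type(sub), value, f"{path}.{name}" if path else name)
        else:
            kwargs[name] = _coerce(value, f.type)
    return cls(**kwargs)


def config_from_dict(data: dict) -> PipelineConfig:
    return _build(PipelineConfig, data or {})


def load_config(path: str | Path | None) -> PipelineConfig:
    """Load a YAML pipeline config; unknown keys are rejected (typo guard)."""
    if path is None:
        return PipelineConfig()
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return config_from_dict(data)


def config_to_dict(cfg) -> dict:
    return dataclasses.asdict(cfg)
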