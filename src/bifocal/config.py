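"""Run configuration: a YAML-serializable description of one pipeline run.
Unknown keys are rejected so a typo never silently falls back to a default."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any

import yaml

from .model import BCNNConfig
from .training import TrainConfig

__all__ = ["RunConfig", "SimulateConfig", "load_run_config", "dump_run_config"]


@dataclass
class SimulateConfig:
    width: int = 2048
    height: int = 2048
    positive_fraction_in_class: float = 0.75
    background_fraction: float = 0.30
    region_seed_count: int = 16
    dots_per_class: int = 75


@dataclass
class TilingConfig:
    stride: int = 50
    foreground_threshold: float = 0.25
    downscale: int = 8  # block-mean tile downsampling before the network


@dataclass
class AugmentConfig:
    enabled: bool = True
    n_types: int = 4


@dataclass
class FusionConfig:
    refine_iterations: int = 3
    positive_class_index: int = 1


@dataclass
class RunConfig:
    simulate: SimulateConfig = field(default_factory=SimulateConfig)
    tiling: TilingConfig = field(default_factory=TilingConfig)
    augment: AugmentConfig = field(default_factory=AugmentConfig)
    model: BCNNConfig = field(default_factory=lambda: BCNNConfig(base_width=8, blocks_per_stage=(1, 1, 1, 1), input_sizes=(64, 32)))
    train: TrainConfig = field(default_factory=TrainConfig)
    fusion: FusionConfig = field(default_factory=FusionConfig)
    rng_seed: int = 0

    def stage_seed(self, stage: str) -> int:
        """Derive a stage-specific seed from the global one, so stages are
        reproducible independently of each other."""
        h = 2166136261
        for ch in stage.encode():
            h = ((h ^ ch) * 16777619) & 0xFFFFFFFF
        return (h ^ self.rng_seed) % (2**31)


def _build(cls, data: dict[str, Any], path: str):
    names = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(names)
    if unknown:
        raise ValueError(f"unknown config key(s) {sorted(unknown)} under {path!r}")
    kwargs = {}
    for key, value in data.items():
        ftype = names[key].type
        if isinstance(value, dict) and dataclasses.is_dataclass(_resolve(names[key])):
            kwargs[key] = _build(_resolve(names[key]), value, f"{path}.{key}")
        elif isinstance(value, list):
            kwargs[key] = tuple(value)
        else:
            kwargs[key] = value
    return cls(**kwargs)


_NESTED = {
    "simulate": SimulateConfig,
    "tiling": TilingConfig,
    "augment": AugmentConfig,
    "model": BCNNConfig,
    "train": TrainConfig,
    "fusion": FusionConfig,
}


def _resolve(f: dataclasses.Field):
    return _NESTED.get(f.name)


def load_run_config(path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError(f"{path}: run config must be a mapping")
    return _build(RunConfig, data, "run")


def dump_run_config(config: RunConfig, path=None) -> str:
    text = yaml.safe_dump(dataclasses.asdict(config), sort_keys=False)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text
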