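"""Declarative pipeline configuration (YAML-backed, CLI-overridable)."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from .imaging import GranularityParams, MuscleSegParams, RatsParams
from .screen import HitThresholds
from .simulate import FieldSimConfig, ScreenSimConfig

__all__ = ["PipelineConfig", "load_config", "dump_config"]


def _to_plain(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _to_plain(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    if isinstance(obj, Path):
        return str(obj)
    return obj


def _from_dict(cls, data: dict):
    kwargs = {}
    for f in dataclasses.fields(cls):
        if f.name not in data:
            continue
        v = data[f.name]
        if dataclasses.is_dataclass(f.type) and isinstance(v, dict):
            v = _from_dict(f.type, v)
        elif isinstance(v, list):
            v = tuple(v)
        kwargs[f.name] = v
    return cls(**kwargs)


@dataclass
class PipelineConfig:
    """Everything a pipeline run needs, in one declarative object."""

    image_dir: str = ""
    plate_map: str = ""
    output_dir: str = "myoscreen_out"
    seed: int = 0
    verbosity: str = "INFO"
    aggregation: str = "pooled"
    zero_policy: str = "epsilon"
    min_neg_wells: int = 4
    min_replicates: int = 3
    segmentation: MuscleSegParams = field(default_factory=MuscleSegParams)
    granularity: GranularityParams = field(default_factory=GranularityParams)
    rats: RatsParams = field(default_factory=RatsParams)
    thresholds: HitThresholds = field(default_factory=HitThresholds)
    field_sim: FieldSimConfig = field(default_factory=FieldSimConfig)
    screen_sim: ScreenSimConfig = field(default_factory=ScreenSimConfig)

    def to_dict(self) -> dict:
        return _to_plain(self)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        sections = {
            "segmentation": MuscleSegParams,
            "granularity": GranularityParams,
            "rats": RatsParams,
            "thresholds": HitThresholds,
            "field_sim": FieldSimConfig,
            "screen_sim": ScreenSimConfig,
        }
        kwargs: dict[str, Any] = {}
        for key, value in data.items():
            if key in sections:
                kwargs[key] = _from_dict(sections[key], value or {})
            else:
                kwargs[key] = value
        return cls(**kwargs)


def load_config(path: str | Path | None) -> PipelineConfig:
    if path is None:
        return PipelineConfig()
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return PipelineConfig.from_dict(data)


def dump_config(config: PipelineConfig) -> str:
    return yaml.safe_dump(config.to_dict(), sort_keys=False)
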