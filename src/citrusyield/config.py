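"""Pipeline configuration: a flat, validated view of every stage's knobs.

Unknown keys are rejected by name so a typo in a config file fails loudly
instead of silently running with defaults.  All defaults reproduce the
published survey settings (camera, fruit size, HSV range, test protocol).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from .camera import DEFAULT_ALTITUDES_M, CameraModel, FruitModel
from .errors import ConfigError
from .segment import HSVRange
from .simulate import SceneSpec

__all__ = ["SegmentationConfig", "StatsConfig", "PipelineConfig", "load_config"]


@dataclass(frozen=True)
class SegmentationConfig:
    method: str = "hsv"               # hsv | ipca | cive | i1
    equalize: bool = True
    hsv_range: HSVRange = field(default_factory=HSVRange)
    tree_strategy: str = "otsu"
    tree_fixed_value: float | None = None
    ipca_variant: str = "verbatim"


@dataclass(frozen=True)
class StatsConfig:
    alpha: float = 0.05
    t_variant: str = "welch"
    test: str = "auto"                # auto | t | wilcoxon
    metric: str = "estimated_fruits"


@dataclass(frozen=True)
class PipelineConfig:
    camera: CameraModel = field(default_factory=CameraModel)
    fruit: FruitModel = field(default_factory=FruitModel)
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)
    simulate: SceneSpec = field(default_factory=SceneSpec)
    altitudes_m: tuple[float, ...] = DEFAULT_ALTITUDES_M
    output_dir: str = "citrusyield_out"


_BLOCKS: dict[str, type] = {
    "camera": CameraModel,
    "fruit": FruitModel,
    "segmentation": SegmentationConfig,
    "stats": StatsConfig,
    "simulate": SceneSpec,
}


def _build(cls: type, block: dict[str, Any], where: str):
    allowed = {f.name for f in dataclasses.fields(cls) if f.init}
    unknown = set(block) - allowed
    if unknown:
        raise ConfigError(
            f"unknown key(s) {sorted(unknown)} in config section {where!r}; "
            f"allowed: {sorted(allowed)}")
    if cls is SegmentationConfig and "hsv_range" in block \
            and isinstance(block["hsv_range"], dict):
        block = dict(block)
        block["hsv_range"] = _build(HSVRange, block["hsv_range"],
                                    "segmentation.hsv_range")
    try:
        return cls(**block)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid config section {where!r}: {exc}") from exc


def load_config(path: str | Path | None = None,
                data: dict[str, Any] | None = None) -> PipelineConfig:
    """Build a :class:`PipelineConfig` from a YAML/JSON file or a dict."""
    if data is None:
        if path is None:
            return PipelineConfig()
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ConfigError("config root must be a mapping")
    top_allowed = set(_BLOCKS) | {"altitudes_m", "output_dir"}
    unknown = set(data) - top_allowed
    if unknown:
        raise ConfigError(f"unknown top-level config key(s) {sorted(unknown)}; "
                          f"allowed: {sorted(top_allowed)}")
    kwargs: dict[str, Any] = {}
    for name, cls in _BLOCKS.items():
        if name in data:
            block = data[name]
            if not isinstance(block, dict):
                raise ConfigError(f"config section {name!r} must be a mapping")
            kwargs[name] = _build(cls, block, name)
    if "altitudes_m" in data:
        alts = tuple(float(a) for a in data["altitudes_m"])
        if not alts or any(a <= 0 for a in alts):
            raise ConfigError("altitudes_m must be a non-empty list of "
                              "positive altitudes")
        kwargs["altitudes_m"] = alts
    if "output_dir" in data:
        kwargs["output_dir"] = str(data["output_dir"])
    return PipelineConfig(**kwargs)
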