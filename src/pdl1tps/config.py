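"""Pipeline configuration: a YAML round-trippable record of every knob."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, fields
from pathlib import Path

import yaml

from .quantify import DEFAULT_MERGE_RADIUS_PX, DEFAULT_TILE_PX
from .router import IntervalScheme
from .segmenter import TrainingConfig

__all__ = ["QuantifyConfig", "PipelineConfig", "load_config", "save_config"]


@dataclass
class QuantifyConfig:
    merge_radius_px: int = DEFAULT_MERGE_RADIUS_PX
    connectivity: int = 1
    tile_px: int = DEFAULT_TILE_PX

    def __post_init__(self):
        if self.merge_radius_px < 0 or self.tile_px < 1:
            raise ValueError("invalid quantification parameters")
        if self.connectivity not in (1, 2):
            raise ValueError("connectivity must be 1 (4-conn) or 2 (8-conn)")


@dataclass
class PipelineConfig:
    training: TrainingConfig = field(default_factory=TrainingConfig)
    quantify: QuantifyConfig = field(default_factory=QuantifyConfig)
    intervals: IntervalScheme = field(default_factory=IntervalScheme)
    seed: int = 0
    verbosity: str = "info"

    def to_dict(self) -> dict:
        d = {"training": asdict(self.training),
             "quantify": asdict(self.quantify),
             "intervals": self.intervals.to_dict(),
             "seed": self.seed, "verbosity": self.verbosity}
        d["training"]["class_weights"] = list(self.training.class_weights)
        return d


def _check_keys(section: str, given: dict, allowed: set[str]) -> None:
    unknown = set(given) - allowed
    if unknown:
        raise ValueError(f"unknown config keys in {section}: {sorted(unknown)}")


def config_from_dict(d: dict) -> PipelineConfig:
    _check_keys("top level", d,
                {"training", "quantify", "intervals", "seed", "verbosity"})
    tr = dict(d.get("training", {}))
    _check_keys("training", tr, {f.name for f in fields(TrainingConfig)})
    if "class_weights" in tr:
        tr["class_weights"] = tuple(tr["class_weights"])
    qu = dict(d.get("quantify", {}))
    _check_keys("quantify", qu, {f.name for f in fields(QuantifyConfig)})
    iv = d.get("intervals")
    return PipelineConfig(
        training=TrainingConfig(**tr),
        quantify=QuantifyConfig(**qu),
        intervals=IntervalScheme.from_dict(iv) if iv else IntervalScheme(),
        seed=int(d.get("seed", 0)),
        verbosity=str(d.get("verbosity", "info")))


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return config_from_dict(data)


def save_config(config: PipelineConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))
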