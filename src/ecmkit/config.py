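"""Pipeline configuration with lossless JSON round-tripping.

Defaults are the reference acquisition/analysis settings: 5x5 filter
masks, 15 orientations, Gaussian sd 0.7, 5 um minimum protrusion length,
90 min protrusion-rate window, 61 um analysis crop, 0.2 um/px.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from .errors import ConfigError


def _from_mapping(cls, data: dict):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = sorted(set(data) - known)
    if unknown:
        raise ConfigError(f"unknown {cls.__name__} keys: {unknown}")
    return cls(**data)


@dataclass
class PreprocessBlock:
    mask_size: int = 5
    n_orientations: int = 15
    gaussian_sd: float = 0.7
    threshold_method: str = "otsu"
    threshold_value: float = 0.0


@dataclass
class MicrostructureBlock:
    max_radius_px: int = 30
    n_thetas: int = 180
    dc_remove: bool = True
    radon_interpolation: str = "linear"
    crop_um: Optional[float] = 61.0
    alignment_source: str = "binary"


@dataclass
class MotilityBlock:
    min_protrusion_um: float = 5.0
    window_min: float = 90.0


@dataclass
class StatsBlock:
    pairs: list = field(default_factory=list)  # e.g. [["speed", "alpha"]]
    exclusions: dict = field(default_factory=dict)  # "speed:alpha" -> [labels]


@dataclass
class PipelineConfig:
    """Top-level configuration for a full analysis run."""

    pixel_size_um: float = 0.2
    preprocess: PreprocessBlock = field(default_factory=PreprocessBlock)
    microstructure: MicrostructureBlock = field(default_factory=MicrostructureBlock)
    motility: MotilityBlock = field(default_factory=MotilityBlock)
    stats: StatsBlock = field(default_factory=StatsBlock)
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        unknown = sorted(set(data) - {f.name for f in dataclasses.fields(cls)})
        if unknown:
            raise ConfigError(f"unknown PipelineConfig keys: {unknown}")
        for key, sub in (
            ("preprocess", PreprocessBlock),
            ("microstructure", MicrostructureBlock),
            ("motility", MotilityBlock),
            ("stats", StatsBlock),
        ):
            if key in data and isinstance(data[key], dict):
                data[key] = _from_mapping(sub, data[key])
        return cls(**data)

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "PipelineConfig":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        return cls.from_dict(json.loads(text))
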