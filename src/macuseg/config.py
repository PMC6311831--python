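"""Pipeline configuration.

All tunable parameters of the three stages and the classifier, with the
method's published constants as defaults (hue band [0.01, 0.1], lesion
fraction 10%, 60/40 train split).  Serializable to JSON and loadable
from JSON or TOML.
"""

from __future__ import annotations

import dataclasses
import json
import tomllib
from dataclasses import dataclass
from pathlib import Path

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    # Stage 1
    hue_lo: float = 0.01
    hue_hi: float = 0.1
    min_object_frac: float = 0.001
    close_radius: int = 5
    exclude_black_border: bool = False
    # Stage 2
    lesion_fraction: float = 0.10
    stretch_p_lo: float = 2.0
    stretch_p_hi: float = 98.0
    # Stage 3
    min_area: int = 5
    ring_width: int = 5
    # Classifier
    train_fraction: float = 0.60
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.hue_lo < self.hue_hi <= 1.0:
            raise ValueError("invalid hue band")
        if not 0.0 < self.lesion_fraction < 1.0:
            raise ValueError("lesion_fraction must lie in (0, 1)")
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must lie in (0, 1)")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        if path.suffix.lower() == ".toml":
            data = tomllib.loads(path.read_text())
        else:
            data = json.loads(path.read_text())
        return cls.from_dict(data)
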