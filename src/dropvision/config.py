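"""Pipeline configuration: every tunable in one serialisable record."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    """All pipeline tunables with their calibrated defaults.

    Optics: ``tau_mean`` (ink absorbance per cm) and ``it_threshold_lx``
    (transmitted-light target).  Segmentation: shape-degree threshold
    ``e_threshold``, structuring-element radius, minimum region area and
    droplet polarity.  Learning: Sarsa rate/discount and the exploration
    schedule.  Unknown keys in a config file are rejected rather than
    ignored, so typos surface immediately.
    """

    # optics
    tau_mean: float = 257.11
    it_threshold_lx: float = 50.0
    # segmentation
    e_threshold: float = 0.67
    se_radius: int = 3
    min_region_area: int = 4
    polarity: str = "dark"
    gradient_method: str = "sobel"
    scale_cm_per_px: float = 0.005
    # contrast adaptation
    alpha: float = 0.1
    gamma: float = 0.9
    epsilon_start: float = 0.9
    epsilon_end: float = 0.05
    episodes: int = 500
    s_gain: float = 2.0
    contrast_step: float = 0.01
    # reproducibility
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))
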