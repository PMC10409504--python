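"""Analysis configuration.

One object carries every tunable constant of the pipeline so that a run is a
pure function of (input files, config, seed).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml


@dataclass
class AnalysisConfig:
    # sampling
    frame_rate_hz: float = 30.0
    # stride segmentation
    segment_length_mm: float | None = None   # None -> body length / 11
    unhook_velocity_threshold: float = 0.2   # mm/s, forward head velocity
    unhook_hold_frames: int = 3              # frames the crossing must hold
    velocity_smooth_frames: int = 5          # moving-average window
    # contraction event detection
    contraction_fraction: float = 0.5        # f in L_ref - f*(L_ref - L_min)
    min_event_frames: int = 2
    # bootstrap
    n_boot: int = 10_000
    seed: int = 0
    sidedness: str = "two"
    between_bins: int = 100
    # model selection
    degree_min: int = 2
    degree_max: int = 10
    # calibration profile name (synthetic data)
    profile: str | None = None

    def __post_init__(self) -> None:
        if self.frame_rate_hz <= 0:
            raise ValueError("frame_rate_hz must be > 0")
        if self.n_boot < 1:
            raise ValueError("n_boot must be >= 1")
        if not (2 <= self.degree_min <= self.degree_max <= 10):
            raise ValueError("polynomial degree range must lie within [2, 10]")
        if self.sidedness not in ("two", "greater", "less"):
            raise ValueError("sidedness must be 'two', 'greater' or 'less'")
        if self.segment_length_mm is not None and self.segment_length_mm <= 0:
            raise ValueError("segment_length_mm must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))
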