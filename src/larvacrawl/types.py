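"""Core data containers.

Conventions: times in seconds, positions and lengths in mm, the anterior
direction is increasing x.  Segments are the abdominal segments A1..A8;
sampling is uniform at a declared frame rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

SEGMENTS = ("A1", "A2", "A3", "A4", "A5", "A6", "A7", "A8")


class FormatError(ValueError):
    """A file or column label does not follow the expected convention."""


class InputError(ValueError):
    """Input data violate a precondition of an operation."""


@dataclass
class LandmarkTrack:
    """Time-indexed 2-D positions (mm) of named body landmarks for one
    animal/episode, uniformly sampled."""

    animal_id: str
    episode_id: str
    frame_rate_hz: float
    positions: dict[str, np.ndarray]  # name -> (n, 2) array, columns x, y

    def __post_init__(self) -> None:
        if self.frame_rate_hz <= 0:
            raise InputError("frame_rate_hz must be positive")
        lengths = {k: np.asarray(v, float).shape for k, v in self.positions.items()}
        self.positions = {k: np.asarray(v, float) for k, v in self.positions.items()}
        n = None
        for k, shape in lengths.items():
            if len(shape) != 2 or shape[1] != 2:
                raise InputError(f"landmark {k!r} must be an (n, 2) array")
            n = shape[0] if n is None else n
            if shape[0] != n:
                raise InputError("all landmarks must share one time base")

    @property
    def n_frames(self) -> int:
        return next(iter(self.positions.values())).shape[0]

    @property
    def t(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.frame_rate_hz

    @property
    def duration(self) -> float:
        return (self.n_frames - 1) / self.frame_rate_hz

    def landmark(self, name: str) -> np.ndarray:
        try:
            return self.positions[name]
        except KeyError:
            raise InputError(f"landmark {name!r} absent from track "
                             f"(has {sorted(self.positions)})") from None

    def body_length_mm(self, head: str = "head", tail: str = "A8_denticle") -> float:
        """Mean head-to-tail landmark distance over the episode."""
        d = self.landmark(head) - self.landmark(tail)
        return float(np.mean(np.hypot(d[:, 0], d[:, 1])))


@dataclass
class Stride:
    """One locomotor cycle, delimited by consecutive mouth-hook unhooking
    moments, with the wave-onset annotation splitting it into the interwave
    phase (unhook -> wave onset) and wave phase (wave onset -> next unhook)."""

    index: int
    t_unhook_start: float
    t_wave_onset: float
    t_unhook_end: float
    stride_length: float
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not (self.t_unhook_start <= self.t_wave_onset <= self.t_unhook_end):
            raise InputError("stride boundaries must be ordered: "
                             "unhook_start <= wave_onset <= unhook_end")
        if self.stride_length < 0:
            raise InputError("stride_length must be >= 0")

    @property
    def stride_duration(self) -> float:
        return self.t_unhook_end - self.t_unhook_start

    @property
    def interwave_duration(self) -> float:
        return self.t_wave_onset - self.t_unhook_start

    @property
    def wave_duration(self) -> float:
        return self.t_unhook_end - self.t_wave_onset

    @property
    def duty_factor(self) -> float:
        return self.interwave_duration / self.stride_duration


@dataclass
class StrideTable:
    """Ordered, non-overlapping strides of one crawling episode."""

    animal_id: str
    episode_id: str
    strides: list[Stride] = field(default_factory=list)

    def __post_init__(self) -> None:
        for a, b in zip(self.strides, self.strides[1:]):
            if b.t_unhook_start < a.t_unhook_end - 1e-9:
                raise InputError("strides must be ordered and non-overlapping")

    def __len__(self) -> int:
        return len(self.strides)

    def __iter__(self):
        return iter(self.strides)

    @property
    def episode_speed(self) -> float:
        """Total stride length divided by total stride duration (mm/s)."""
        total_t = sum(s.stride_duration for s in self.strides)
        if total_t == 0:
            raise InputError("zero total stride duration")
        return sum(s.stride_length for s in self.strides) / total_t

    def to_frame(self) -> pd.DataFrame:
        rows = [dict(animal_id=self.animal_id, episode_id=self.episode_id,
                     index=s.index, t_unhook_start=s.t_unhook_start,
                     t_wave_onset=s.t_wave_onset, t_unhook_end=s.t_unhook_end,
                     stride_length=s.stride_length,
                     stride_duration=s.stride_duration,
                     interwave_duration=s.interwave_duration,
                     wave_duration=s.wave_duration,
                     duty_factor=s.duty_factor,
                     degenerate=s.degenerate)
                for s in self.strides]
        return pd.DataFrame(rows)


@dataclass
class MuscleTrace:
    """Length of one muscle (mm) over time at a fixed frame rate."""

    muscle: str            # e.g. LT2, VL4, DO1, VL2
    segment: str           # A1..A8
    side: str | None       # "L", "R" or None
    length: np.ndarray
    frame_rate_hz: float
    animal_id: str = ""
    episode_id: str = ""

    def __post_init__(self) -> None:
        self.length = np.asarray(self.length, float)
        if self.frame_rate_hz <= 0:
            raise InputError("frame_rate_hz must be positive")
        if np.any(self.length <= 0):
            raise InputError("muscle lengths must be positive")

    @property
    def t(self) -> np.ndarray:
        return np.arange(self.length.size) / self.frame_rate_hz

    @property
    def label(self) -> str:
        side = f"_{self.side}" if self.side else ""
        return f"{self.muscle}_{self.segment}{side}"


@dataclass
class ContractionEvent:
    """One contraction episode of a muscle.

    The amplitude is the relative shortening (L_ref - L_min) / L_ref, where
    L_ref is the local pre-contraction maximum length.
    """

    muscle: str
    segment: str
    side: str | None
    t_onset: float
    t_offset: float
    L_min: float
    L_ref: float

    def __post_init__(self) -> None:
        if self.t_offset <= self.t_onset:
            raise InputError("t_offset must exceed t_onset")
        if self.L_min > self.L_ref:
            raise InputError("L_min must not exceed L_ref")

    @property
    def duration(self) -> float:
        return self.t_offset - self.t_onset

    @property
    def amplitude(self) -> float:
        return (self.L_ref - self.L_min) / self.L_ref

    @property
    def t_center(self) -> float:
        return 0.5 * (self.t_onset + self.t_offset)


@dataclass
class CalciumTrace:
    """Delta-F/F of one region of interest (cell type x segment)."""

    cell_type: str         # nSyb, A31c, A26f, ...
    segment: str
    dff: np.ndarray
    frame_rate_hz: float
    recording_id: str = ""

    def __post_init__(self) -> None:
        self.dff = np.asarray(self.dff, float)
        if not np.all(np.isfinite(self.dff)):
            raise InputError("calcium trace contains non-finite values")
        if self.frame_rate_hz <= 0:
            raise InputError("frame_rate_hz must be positive")

    @property
    def t(self) -> np.ndarray:
        return np.arange(self.dff.size) / self.frame_rate_hz

    @property
    def label(self) -> str:
        return f"{self.cell_type}_{self.segment}"


@dataclass
class AlignedTraceSet:
    """Traces resampled onto a normalized cycle axis.

    Anchor A's peak maps to normalized time 0 and anchor B's peak to 1 in
    every cycle; each trace is min-max normalized over the whole recording.
    """

    grid: np.ndarray                       # normalized time axis
    cycles: dict[str, np.ndarray]          # label -> (n_cycles, grid) array
    anchor_a: str
    anchor_b: str
    normalization: dict[str, tuple[float, float]]  # label -> (min, max)

    @property
    def n_cycles(self) -> int:
        return next(iter(self.cycles.values())).shape[0]

    def mean(self, label: str) -> np.ndarray:
        return self.cycles[label].mean(axis=0)


@dataclass
class CorrelationResult:
    """Pearson correlation between two named variables."""

    x_label: str
    y_label: str
    r: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 3:
            raise InputError("correlation requires n >= 3")
        if abs(self.r) > 1 + 1e-12:
            raise InputError("|r| must not exceed 1")


@dataclass
class HierarchicalDataset:
    """Nested scalar measurements: group -> animals -> trial values."""

    group: str
    animals: list[np.ndarray]
    animal_ids: list[str] | None = None

    def __post_init__(self) -> None:
        if not self.animals:
            raise InputError("dataset needs at least one animal")
        self.animals = [np.asarray(a, float) for a in self.animals]
        for a in self.animals:
            if a.size == 0:
                raise InputError("every animal needs at least one trial")
            if not np.all(np.isfinite(a)):
                raise InputError("trial values must be finite")
        if self.animal_ids is None:
            self.animal_ids = [f"animal{i}" for i in range(len(self.animals))]

    @property
    def n_animals(self) -> int:
        return len(self.animals)

    @property
    def trial_counts(self) -> list[int]:
        return [a.size for a in self.animals]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for aid, vals in zip(self.animal_ids, self.animals):
            for j, v in enumerate(vals):
                rows.append(dict(group=self.group, animal=aid, trial=j, value=v))
        return pd.DataFrame(rows)


@dataclass
class BootstrapResult:
    """Outcome of a hierarchical bootstrap test."""

    kind: str                    # "within" or "between"
    n_boot: int
    seed: int
    sidedness: str               # "two", "greater", "less"
    observed: float              # mu (within) or mu_a - mu_b (between)
    boot_mean: float
    boot_sd: float
    quantiles: Mapping[str, float]
    p_value: float
    stars: str
    degenerate: bool = False
    p_value_pairwise: float | None = None   # binning-free oracle (between only)

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise InputError("p_value must lie in [0, 1]")

    def to_dict(self) -> dict:
        d = dict(kind=self.kind, n_boot=self.n_boot, seed=self.seed,
                 sidedness=self.sidedness, observed=self.observed,
                 boot_mean=self.boot_mean, boot_sd=self.boot_sd,
                 quantiles=dict(self.quantiles), p_value=self.p_value,
                 stars=self.stars, degenerate=self.degenerate)
        if self.p_value_pairwise is not None:
            d["p_value_pairwise"] = self.p_value_pairwise
        return d
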