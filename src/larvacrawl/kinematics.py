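"""Stride detection and wave/interwave phase segmentation.

A stride runs from one mouth-hook unhooking moment to the next.  Unhooking
is detected as the onset of sustained forward head motion; the wave onset
within a stride is the first time the A8 denticle has moved half a segmental
length from its previous landing position.  Stride length is the distance
between consecutive A8 denticle landing positions.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .types import InputError, LandmarkTrack, Stride, StrideTable

HEAD = "head"
TAIL = "A8_denticle"
SEGMENTS_PER_BODY = 11  # T1-T3 + A1-A8


def _smooth(x: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return x
    kernel = np.ones(window) / window
    pad = window // 2
    xp = np.pad(x, pad, mode="edge")
    out = np.convolve(xp, kernel, mode="same")[pad:pad + x.size]
    return out


def forward_velocity(track: LandmarkTrack, landmark: str,
                     smooth_frames: int = 1) -> np.ndarray:
    """Forward (x) velocity of a landmark in mm/s, optionally smoothed."""
    x = track.landmark(landmark)[:, 0]
    v = np.gradient(x) * track.frame_rate_hz
    return _smooth(v, smooth_frames)


def segment_length(track: LandmarkTrack, config: AnalysisConfig) -> float:
    """Segmental length: configured value, else body length / 11."""
    if config.segment_length_mm is not None:
        return config.segment_length_mm
    return track.body_length_mm(HEAD, TAIL) / SEGMENTS_PER_BODY


def detect_unhook_times(track: LandmarkTrack, config: AnalysisConfig) -> np.ndarray:
    """Unhooking moments: upward threshold crossings of smoothed forward head
    velocity held for a minimum number of frames, refined backwards to the
    start of raw head motion."""
    thr = config.unhook_velocity_threshold
    hold = config.unhook_hold_frames
    v_raw = forward_velocity(track, HEAD, 1)
    v = forward_velocity(track, HEAD, config.velocity_smooth_frames)
    # noise floor of the raw velocity, estimated from the still frames
    still = v < 0.5 * thr
    if np.any(still):
        resid = v_raw[still] - np.median(v_raw[still])
        sigma = 1.4826 * np.median(np.abs(resid))
    else:
        sigma = 0.0
    floor = max(0.25 * thr, 3.0 * sigma)
    above = v >= thr
    onsets = []
    i = 0
    n = v.size
    while i < n:
        if above[i] and (i == 0 or not above[i - 1]):
            j = i
            while j < n and above[j]:
                j += 1
            if j - i >= hold:
                # back off on the smoothed trace, then advance to the first
                # raw-velocity frame above the noise floor (the smoothing
                # window otherwise shifts the onset early)
                k = i
                while k > 0 and v[k - 1] > 0.5 * thr:
                    k -= 1
                while k < i and v_raw[k] <= floor:
                    k += 1
                if not onsets or k > onsets[-1]:
                    onsets.append(k)
            i = j
        else:
            i += 1
    return np.asarray(onsets) / track.frame_rate_hz


def _tail_plateaus(track: LandmarkTrack, config: AnalysisConfig):
    """Stationary plateaus of the A8 denticle: (start_t, end_t, level_x)."""
    fps = track.frame_rate_hz
    speed = np.abs(forward_velocity(track, TAIL, config.velocity_smooth_frames))
    still = speed < config.unhook_velocity_threshold
    plateaus = []
    x = track.landmark(TAIL)[:, 0]
    i = 0
    n = still.size
    while i < n:
        if still[i]:
            j = i
            while j < n and still[j]:
                j += 1
            if j - i >= config.unhook_hold_frames:
                level = float(np.median(x[i:j]))
                plateaus.append((i / fps, (j - 1) / fps, level))
            i = j
        else:
            i += 1
    return plateaus


def _landing_before(track, plateaus, t: float,
                    config: AnalysisConfig) -> float | None:
    """A8 landing position in effect at time t: the level of the last
    plateau starting at or before t.  When that plateau extends past t
    (e.g. a slow sub-threshold drift), only its portion up to t is used."""
    found = None
    for start, end, lev in plateaus:
        if start <= t:
            found = (start, end, lev)
        else:
            break
    if found is None:
        return None
    start, end, lev = found
    if end > t:
        fps = track.frame_rate_hz
        x = track.landmark(TAIL)[:, 0]
        i0 = int(round(start * fps))
        i1 = max(i0 + 1, int(round(t * fps)) + 1)
        lev = float(np.median(x[i0:i1]))
    return lev


def detect_strides(track: LandmarkTrack, config: AnalysisConfig) -> StrideTable:
    """Detect stride boundaries (no wave-onset annotation yet).

    Returns a StrideTable whose strides have ``t_wave_onset`` provisionally
    set to ``t_unhook_start``; call :func:`annotate_wave_onsets` next.
    Incomplete first/last strides are discarded by construction (a stride
    needs two unhooking events).
    """
    for lm in (HEAD, TAIL):
        track.landmark(lm)  # raises InputError when missing
    unhooks = detect_unhook_times(track, config)
    table = StrideTable(track.animal_id, track.episode_id, [])
    if unhooks.size < 2:
        warnings.warn(f"fewer than two unhooking events in "
                      f"{track.animal_id}/{track.episode_id}; empty table")
        return table
    plateaus = _tail_plateaus(track, config)
    strides = []
    for k, (t0, t1) in enumerate(zip(unhooks[:-1], unhooks[1:])):
        before = _landing_before(track, plateaus, t0, config)
        after = _landing_before(track, plateaus, t1, config)
        if before is None or after is None:
            continue
        length = max(0.0, after - before)
        strides.append(Stride(k, t0, t0, t1, length))
    table.strides = strides
    return table


def annotate_wave_onset(track: LandmarkTrack, stride: Stride,
                        config: AnalysisConfig) -> float:
    """First time within the stride at which the A8 denticle has moved half
    a segmental length from its previous landing position (clipped into the
    stride).  Marks the stride degenerate when the displacement never
    reaches the threshold."""
    fps = track.frame_rate_hz
    half_seg = 0.5 * segment_length(track, config)
    plateaus = _tail_plateaus(track, config)
    landing = _landing_before(track, plateaus, stride.t_unhook_start, config)
    x = track.landmark(TAIL)[:, 0]
    i0 = int(round(stride.t_unhook_start * fps))
    i1 = int(round(stride.t_unhook_end * fps))
    if landing is None:
        landing = x[i0]
    disp = x[i0:i1 + 1] - landing
    hits = np.nonzero(disp >= half_seg)[0]
    if hits.size == 0:
        stride.degenerate = True
        return stride.t_unhook_end
    k = hits[0]
    if k > 0 and disp[k] > disp[k - 1]:
        # sub-frame crossing time by linear interpolation
        frac = (half_seg - disp[k - 1]) / (disp[k] - disp[k - 1])
        onset = (i0 + k - 1 + frac) / fps
    else:
        onset = (i0 + k) / fps
    return float(np.clip(onset, stride.t_unhook_start, stride.t_unhook_end))


def annotate_wave_onsets(track: LandmarkTrack, table: StrideTable,
                         config: AnalysisConfig) -> StrideTable:
    for s in table.strides:
        s.t_wave_onset = annotate_wave_onset(track, s, config)
    return table


def compute_stride_metrics(table: StrideTable) -> pd.DataFrame:
    """Per-stride metrics plus episode summary columns.

    Episode speed is total stride length / total stride duration; stride
    frequency is the reciprocal of the mean stride duration.  Degenerate
    strides (no wave onset) are excluded from phase statistics downstream
    but retained here with their flag.
    """
    if len(table) == 0:
        raise InputError("empty stride table")
    df = table.to_frame()
    df["episode_speed"] = table.episode_speed
    df["episode_mean_stride_length"] = df["stride_length"].mean()
    df["episode_stride_frequency"] = 1.0 / df["stride_duration"].mean()
    return df


def analyze_track(track: LandmarkTrack, config: AnalysisConfig) -> StrideTable:
    """Full segmentation for one track: strides + wave onsets."""
    table = detect_strides(track, config)
    return annotate_wave_onsets(track, table, config)
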