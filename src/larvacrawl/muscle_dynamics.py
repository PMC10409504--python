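"""Contraction-event extraction from muscle-length traces and their relation
to the stride phases."""

from __future__ import annotations

import warnings

import numpy as np
from scipy.signal import find_peaks

from .config import AnalysisConfig
from .types import ContractionEvent, InputError, MuscleTrace, StrideTable
from . import phase_stats

_MIN_PROMINENCE_FRAC = 0.08  # of the trace's full range


def detect_contractions(trace: MuscleTrace,
                        config: AnalysisConfig) -> list[ContractionEvent]:
    """Extract contraction events.

    Each local length minimum with its preceding local maximum ``L_ref``
    defines a threshold level ``L_ref - f*(L_ref - L_min)``; the event's
    onset/offset are the (linearly interpolated) crossings of that level on
    either side of the minimum.  Events shorter than the minimum duration
    are discarded.  A constant trace yields no events.
    """
    y = trace.length
    fps = trace.frame_rate_hz
    rng_y = float(y.max() - y.min())
    if rng_y <= 0:
        return []
    f = config.contraction_fraction
    minima, _ = find_peaks(-y, prominence=_MIN_PROMINENCE_FRAC * rng_y)
    events: list[ContractionEvent] = []
    prev_min = 0
    for m in minima:
        left_seg = y[prev_min:m + 1]
        ref_idx = prev_min + int(np.argmax(left_seg))
        L_ref = float(y[ref_idx])
        L_min = float(y[m])
        if L_ref <= L_min:
            prev_min = m
            continue
        level = L_ref - f * (L_ref - L_min)
        onset = _cross_down(y, ref_idx, m, level)
        offset = _cross_up(y, m, level)
        prev_min = m
        if onset is None or offset is None:
            continue
        duration = (offset - onset) / fps
        if duration < config.min_event_frames / fps:
            continue
        events.append(ContractionEvent(trace.muscle, trace.segment, trace.side,
                                       onset / fps, offset / fps,
                                       L_min, L_ref))
    return events


def _cross_down(y, start, stop, level):
    """Interpolated index where y falls through `level` in [start, stop]."""
    for i in range(stop, start, -1):
        if y[i - 1] >= level > y[i]:
            frac = (y[i - 1] - level) / (y[i - 1] - y[i])
            return (i - 1) + frac
        if y[i] >= level:
            return None
    return None


def _cross_up(y, start, level):
    for i in range(start, y.size - 1):
        if y[i] < level <= y[i + 1]:
            frac = (level - y[i]) / (y[i + 1] - y[i])
            return i + frac
    return None


def normalize_min_length(trace: MuscleTrace,
                         baseline_window: tuple[float, float]) -> np.ndarray:
    """Series divided by the minimum length inside the baseline window
    (e.g. the light-off period of an optogenetic trial)."""
    t0, t1 = baseline_window
    fps = trace.frame_rate_hz
    # half-open window [t0, t1)
    i0 = max(0, int(np.ceil(t0 * fps)))
    i1 = min(trace.length.size, int(np.ceil(t1 * fps)))
    if i1 <= i0:
        raise InputError("empty baseline window")
    base = float(trace.length[i0:i1].min())
    return trace.length / base


def _interval_overlap(a0, a1, b0, b1) -> float:
    return max(0.0, min(a1, b1) - max(a0, b0))


def phase_overlap(events: list[ContractionEvent],
                  strides: StrideTable) -> dict:
    """Fractions of total contraction time spent in the interwave phase, the
    wave phase, and outside any stride."""
    total = sum(e.duration for e in events)
    if total == 0 or len(strides) == 0:
        warnings.warn("no temporal overlap between events and strides")
        return dict(interwave=np.nan, wave=np.nan, outside=np.nan,
                    total_event_time=total, defined=False)
    inter = wave = 0.0
    for e in events:
        for s in strides:
            inter += _interval_overlap(e.t_onset, e.t_offset,
                                       s.t_unhook_start, s.t_wave_onset)
            wave += _interval_overlap(e.t_onset, e.t_offset,
                                      s.t_wave_onset, s.t_unhook_end)
    outside = total - inter - wave
    return dict(interwave=inter / total, wave=wave / total,
                outside=outside / total, total_event_time=total, defined=True)


def pair_events_to_strides(events: list[ContractionEvent],
                           strides: StrideTable):
    """Assign each event to the stride whose interwave interval overlaps it
    most (ties -> earlier stride).  Events overlapping no interwave interval
    are left unmatched."""
    pairs, unmatched = [], []
    for e in events:
        best, best_ov = None, 0.0
        for s in strides:
            ov = _interval_overlap(e.t_onset, e.t_offset,
                                   s.t_unhook_start, s.t_wave_onset)
            if ov > best_ov:
                best, best_ov = s, ov
        if best is None:
            unmatched.append(e)
        else:
            pairs.append((e, best))
    return pairs, unmatched


def contraction_phase_correlations(events: list[ContractionEvent],
                                   strides: StrideTable) -> dict:
    """Pearson correlations of contraction duration and amplitude against
    the interwave, wave and stride durations of the paired strides."""
    pairs, unmatched = pair_events_to_strides(events, strides)
    if len(pairs) < 3:
        raise InputError("need at least 3 matched event-stride pairs")
    dur = np.array([e.duration for e, _ in pairs])
    amp = np.array([e.amplitude for e, _ in pairs])
    iw = np.array([s.interwave_duration for _, s in pairs])
    wv = np.array([s.wave_duration for _, s in pairs])
    st = np.array([s.stride_duration for _, s in pairs])
    out = {"n_pairs": len(pairs), "n_unmatched": len(unmatched)}
    for yname, y in (("duration", dur), ("amplitude", amp)):
        for xname, x in (("interwave_duration", iw), ("wave_duration", wv),
                         ("stride_duration", st)):
            res = phase_stats.pearson_r(x, y, x_label=xname, y_label=yname)
            out[f"r_{yname}_{xname}"] = res.r
    return out
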