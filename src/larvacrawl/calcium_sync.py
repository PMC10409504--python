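"""Normalization, peak alignment and cross-correlation of segmental calcium
traces.

Traces are min-max normalized over the whole recording; cycles are aligned
so that anchor A's activity peak maps to normalized time 0 and anchor B's
to 1.  Intersegmental lags come from time-lagged Pearson cross-correlation
curves averaged across recordings with the Fisher-z correction.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.signal import find_peaks

from .types import AlignedTraceSet, CalciumTrace, InputError

R_CLIP = 1.0 - 1e-6
DEFAULT_GRID = 100


def dff_from_raw(f: np.ndarray, percentile: float = 10.0) -> np.ndarray:
    """(F - F0)/F0 with F0 the given percentile of the raw trace (helper for
    raw-fluorescence inputs; the core path consumes dF/F directly)."""
    f = np.asarray(f, float)
    f0 = np.percentile(f, percentile)
    if f0 <= 0:
        raise InputError("baseline percentile must be positive")
    return (f - f0) / f0


def minmax_normalize(trace: CalciumTrace) -> tuple[np.ndarray, tuple[float, float]]:
    lo = float(trace.dff.min())
    hi = float(trace.dff.max())
    if hi <= lo:
        raise InputError(f"flat trace {trace.label}: cannot normalize")
    return (trace.dff - lo) / (hi - lo), (lo, hi)


def detect_peaks(trace: CalciumTrace, prominence_frac: float = 0.2,
                 min_interval_s: float = 0.5) -> np.ndarray:
    """Peak times (s): local maxima above a prominence threshold (fraction of
    the trace range) separated by a minimum interval."""
    rng = trace.dff.max() - trace.dff.min()
    if rng <= 0:
        return np.array([])
    distance = max(1, int(round(min_interval_s * trace.frame_rate_hz)))
    idx, _ = find_peaks(trace.dff, prominence=prominence_frac * rng,
                        distance=distance)
    return idx / trace.frame_rate_hz


def normalize_and_align(traces: list[CalciumTrace], anchor_a: str,
                        anchor_b: str, grid_points: int = DEFAULT_GRID,
                        prominence_frac: float = 0.2,
                        min_interval_s: float = 0.5) -> AlignedTraceSet:
    """Min-max normalize every trace and resample each cycle onto a common
    normalized time axis anchored at the two anchor ROIs' peaks.

    A cycle is a consecutive pair (peak of anchor A, next peak of anchor B);
    cycles missing either anchor peak are dropped with a warning.
    """
    by_label = {tr.label: tr for tr in traces}
    for a in (anchor_a, anchor_b):
        if a not in by_label:
            raise InputError(f"anchor trace {a!r} not present")
    peaks_a = detect_peaks(by_label[anchor_a], prominence_frac, min_interval_s)
    peaks_b = detect_peaks(by_label[anchor_b], prominence_frac, min_interval_s)
    if peaks_a.size == 0 or peaks_b.size == 0:
        raise InputError("anchor trace has no detectable peak")
    cycles = []
    for ta in peaks_a:
        later = peaks_b[peaks_b > ta]
        if later.size:
            tb = later[0]
            # skip if another anchor-A peak comes first (missing B peak)
            if not np.any((peaks_a > ta) & (peaks_a < tb)):
                cycles.append((ta, tb))
    dropped = peaks_a.size - len(cycles)
    if dropped > 0:
        warnings.warn(f"{dropped} cycle(s) dropped: missing anchor peak")
    if not cycles:
        raise InputError("no complete anchor cycle found")
    grid = np.linspace(0.0, 1.0, grid_points)
    out, norm = {}, {}
    for label, tr in by_label.items():
        z, (lo, hi) = minmax_normalize(tr)
        t = tr.t
        rows = [np.interp(ta + grid * (tb - ta), t, z) for ta, tb in cycles]
        out[label] = np.asarray(rows)
        norm[label] = (lo, hi)
    return AlignedTraceSet(grid, out, anchor_a, anchor_b, norm)


def lagged_xcorr(trace_a: CalciumTrace, trace_b: CalciumTrace,
                 max_lag_s: float) -> tuple[np.ndarray, np.ndarray]:
    """Pearson r between A and B shifted by each lag (one-frame steps).

    Positive lag means B is delayed relative to A.  Lags whose overlap has
    fewer than 3 samples or zero variance are NaN.
    """
    if trace_a.frame_rate_hz != trace_b.frame_rate_hz:
        raise InputError("traces must share a frame rate")
    fps = trace_a.frame_rate_hz
    a, b = trace_a.dff, trace_b.dff
    max_lag = int(round(max_lag_s * fps))
    lags = np.arange(-max_lag, max_lag + 1)
    rs = np.full(lags.size, np.nan)
    for i, k in enumerate(lags):
        if k >= 0:
            xa, xb = a[:a.size - k] if k else a, b[k:]
        else:
            xa, xb = a[-k:], b[:k]
        m = min(xa.size, xb.size)
        xa, xb = xa[:m], xb[:m]
        if m < 3 or xa.std() == 0 or xb.std() == 0:
            continue
        c = np.corrcoef(xa, xb)[0, 1]
        rs[i] = c
    return lags / fps, rs


def fisher_z_mean(r_values) -> float:
    """tanh(mean(atanh(r))): the Fisher-z corrected mean correlation."""
    r = np.asarray(list(r_values), float)
    if r.size == 0:
        raise InputError("empty correlation collection")
    if np.any(np.abs(r) > 1):
        raise InputError("|r| must not exceed 1")
    r = np.clip(r, -R_CLIP, R_CLIP)
    return float(np.tanh(np.mean(np.arctanh(r))))


def intersegmental_lag(recordings: list[list[CalciumTrace]], reference: str,
                       max_lag_s: float = 2.0) -> dict:
    """Per-segment lag of each ROI against the reference segment's ROI.

    ``recordings`` is a list of recordings, each a list of traces of one
    cell type across segments.  Cross-correlation curves are computed per
    recording and averaged across recordings per lag with the Fisher-z
    correction; the lag estimate is the argmax of the averaged curve
    (ties -> smallest absolute lag).
    """
    curves: dict[str, list[np.ndarray]] = {}
    lags_s = None
    for traces in recordings:
        by_seg = {tr.segment: tr for tr in traces}
        if reference not in by_seg:
            raise InputError(f"reference segment {reference!r} absent")
        ref = by_seg[reference]
        for seg, tr in by_seg.items():
            lags_s, rs = lagged_xcorr(ref, tr, max_lag_s)
            curves.setdefault(seg, []).append(rs)
    out = {"reference": reference, "lags_s": lags_s, "curves": {}, "lag": {}}
    for seg, rows in curves.items():
        arr = np.asarray(rows)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            mean_curve = np.array([
                fisher_z_mean(col[np.isfinite(col)]) if np.any(np.isfinite(col))
                else np.nan for col in arr.T])
        out["curves"][seg] = mean_curve
        if not np.any(np.isfinite(mean_curve)):
            out["lag"][seg] = None
            continue
        finite = np.where(np.isfinite(mean_curve), mean_curve, -np.inf)
        best = np.max(finite)
        if np.all(finite == finite[np.isfinite(mean_curve)][0]):
            out["lag"][seg] = None   # flat curve: lag undefined
            continue
        candidates = np.nonzero(finite >= best - 1e-12)[0]
        idx = candidates[np.argmin(np.abs(lags_s[candidates]))]
        out["lag"][seg] = float(lags_s[idx])
    return out


def relative_peak_times(target: CalciumTrace, bracket: CalciumTrace,
                        prominence_frac: float = 0.2,
                        min_interval_s: float = 0.5) -> np.ndarray:
    """Positions of target peaks between consecutive bracket peaks, on the
    normalized axis where the first bracket peak is 0 and the second is 1."""
    pb = detect_peaks(bracket, prominence_frac, min_interval_s)
    if pb.size < 2:
        raise InputError("bracket trace needs at least two peaks")
    pt = detect_peaks(target, prominence_frac, min_interval_s)
    out = []
    for t0, t1 in zip(pb[:-1], pb[1:]):
        inside = pt[(pt >= t0) & (pt <= t1)]
        out.extend((inside - t0) / (t1 - t0))
    if not out:
        warnings.warn("no target peak enclosed by bracket peaks")
    return np.asarray(out)
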