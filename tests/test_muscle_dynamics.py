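"""Contraction-event detection, normalization, phase overlap and pairing."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from larvacrawl.config import AnalysisConfig
from larvacrawl import muscle_dynamics as md
from larvacrawl.synthetic import simulate_crawl_episode, simulate_muscle_traces
from larvacrawl.types import ContractionEvent, InputError, MuscleTrace, \
    Stride, StrideTable

FPS = 30.0
CFG = AnalysisConfig(frame_rate_hz=FPS, segment_length_mm=4.0 / 11.0)


def triangular_trace(lo=0.6, hi=1.0, dip_s=0.6, fps=FPS):
    """Symmetric triangular dip hi -> lo -> hi over dip_s seconds."""
    n_half = int(dip_s * fps / 2)
    down = np.linspace(hi, lo, n_half + 1)
    up = np.linspace(lo, hi, n_half + 1)[1:]
    y = np.concatenate([np.full(30, hi), down, up, np.full(30, hi)])
    return MuscleTrace("LT2", "A4", None, y, fps)


def test_constant_trace_has_no_events():
    tr = MuscleTrace("LT2", "A4", None, np.full(100, 1.0), FPS)
    assert md.detect_contractions(tr, CFG) == []


def test_triangular_dip_closed_form():
    """1.0 -> 0.6 -> 1.0 over 0.6 s at f = 0.5: the 0.8 mm level is crossed
    0.15 s either side of the minimum -> duration 0.3 s, amplitude 0.4."""
    tr = triangular_trace()
    events = md.detect_contractions(tr, CFG)
    assert len(events) == 1
    e = events[0]
    assert e.duration == pytest.approx(0.3, abs=1.5 / FPS)
    assert e.amplitude == pytest.approx(0.4, abs=1e-9)
    assert e.L_min == pytest.approx(0.6)
    assert e.L_ref == pytest.approx(1.0)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(scale=st.floats(0.1, 50.0))
def test_amplitude_and_duration_invariant_to_scaling(scale):
    tr = triangular_trace()
    scaled = MuscleTrace("LT2", "A4", None, tr.length * scale, FPS)
    e0 = md.detect_contractions(tr, CFG)[0]
    e1 = md.detect_contractions(scaled, CFG)[0]
    assert e1.amplitude == pytest.approx(e0.amplitude, abs=1e-12)
    assert e1.duration == pytest.approx(e0.duration, abs=1e-12)


def test_raised_cosine_half_width_recovered(noise_free_muscle_profile):
    """The generator's raised-cosine pulses cross half depth exactly one
    half-width either side of the minimum, so detection at f = 0.5 recovers
    the planned contraction duration."""
    track, gt = simulate_crawl_episode(noise_free_muscle_profile, seed=2)
    traces = simulate_muscle_traces(noise_free_muscle_profile, gt, seed=2)
    lt2 = next(tr for tr in traces if tr.muscle == "LT2")
    events = md.detect_contractions(lt2, CFG)
    assert len(events) == gt.n_strides
    for e, C in zip(events, gt.lt2_duration):
        assert e.duration == pytest.approx(C, abs=1.0 / FPS)
    # same trace, same result (idempotent)
    again = md.detect_contractions(lt2, CFG)
    assert [(e.t_onset, e.t_offset) for e in again] == \
        [(e.t_onset, e.t_offset) for e in events]


def test_normalize_min_length_examples():
    y = np.concatenate([np.full(30, 1.0), np.full(10, 0.8),
                        np.full(30, 1.0), np.full(10, 0.6), np.full(20, 1.0)])
    tr = MuscleTrace("LT2", "A4", None, y, FPS)
    norm = md.normalize_min_length(tr, (0.0, 70 / FPS))
    assert norm.min() == pytest.approx(0.6 / 0.8)
    # flat trace at the baseline minimum -> all ones
    flat = MuscleTrace("LT2", "A4", None, np.full(60, 0.8), FPS)
    np.testing.assert_allclose(md.normalize_min_length(flat, (0.0, 1.0)), 1.0)
    # rescaling by the baseline minimum recovers the original
    np.testing.assert_allclose(norm * 0.8, y, atol=1e-12)
    with pytest.raises(InputError):
        md.normalize_min_length(tr, (1.0, 1.0))


def make_stride_table():
    return StrideTable("a", "e", [Stride(0, 0.0, 1.0, 2.0, 0.8),
                                  Stride(1, 2.0, 3.0, 4.0, 0.8)])


def test_phase_overlap_event_inside_interwave():
    ev = [ContractionEvent("LT2", "A4", None, 0.2, 0.8, 0.6, 1.0)]
    frac = md.phase_overlap(ev, make_stride_table())
    assert frac["interwave"] == pytest.approx(1.0)
    assert frac["wave"] == pytest.approx(0.0)


def test_phase_overlap_event_straddling_onset():
    ev = [ContractionEvent("LT2", "A4", None, 0.5, 1.5, 0.6, 1.0)]
    frac = md.phase_overlap(ev, make_stride_table())
    assert frac["interwave"] == pytest.approx(0.5)
    assert frac["wave"] == pytest.approx(0.5)


def test_phase_overlap_no_overlap_flagged():
    ev = [ContractionEvent("LT2", "A4", None, 10.0, 11.0, 0.6, 1.0)]
    with pytest.warns(UserWarning):
        frac = md.phase_overlap(ev, StrideTable("a", "e", []))
    assert not frac["defined"]


def test_event_pairing_prefers_largest_interwave_overlap():
    table = make_stride_table()
    ev = [ContractionEvent("LT2", "A4", None, 0.8, 2.4, 0.6, 1.0),
          ContractionEvent("LT2", "A4", None, 1.2, 1.8, 0.6, 1.0)]
    pairs, unmatched = md.pair_events_to_strides(ev, table)
    # first event overlaps stride 1's interwave (0.4 s) more than stride 0's
    # (0.2 s); the second lies entirely in the wave phase -> unmatched
    assert [s.index for _, s in pairs] == [1]
    assert len(unmatched) == 1


def test_shuffling_events_across_strides_destroys_correlation():
    """Permuting contraction durations across strides leaves only chance
    correlation with the interwave durations."""
    from larvacrawl.synthetic import load_profile
    from larvacrawl import study
    df = study.lt2_stride_pairs(load_profile("fig1_sideview"), seed=1)
    rng = np.random.default_rng(0)
    rs = []
    for _ in range(5):
        shuffled = rng.permutation(df["contraction_duration"].to_numpy())
        rs.append(np.corrcoef(shuffled, df["interwave_duration"])[0, 1])
    n = len(df)
    assert np.all(np.abs(rs) <= 3.5 / np.sqrt(n))


def test_zero_coupling_noise_gives_perfect_duration_correlation(
        noise_free_muscle_profile):
    """With unit coupling and no noise the contraction duration equals the
    interwave duration, so their correlation is 1."""
    p = noise_free_muscle_profile.copy()
    # vary interwave across strides so a correlation exists (noise small
    # enough that every contraction stays detectable)
    p.kinematics["interwave_noise_stride"] = 0.06
    p.counts["strides_per_episode"] = 8
    track, gt = simulate_crawl_episode(p, seed=4)
    np.testing.assert_allclose(gt.lt2_duration, gt.interwave_duration,
                               atol=1e-12)
    from larvacrawl import kinematics
    table = kinematics.analyze_track(track, CFG)
    traces = simulate_muscle_traces(p, gt, seed=4)
    lt2 = next(tr for tr in traces if tr.muscle == "LT2")
    events = md.detect_contractions(lt2, CFG)
    out = md.contraction_phase_correlations(events, table)
    assert out["r_duration_interwave_duration"] > 0.97
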