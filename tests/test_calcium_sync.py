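"""Calcium-trace normalization, alignment, cross-correlation and lags."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from larvacrawl import calcium_sync as cs
from larvacrawl.synthetic import simulate_calcium
from larvacrawl.types import CalciumTrace, InputError

FPS = 10.0


def burst_trace(peak_times, n=400, fps=FPS, cell="X", seg="A4", noise=0.0,
                seed=0, amp=1.0):
    rng = np.random.default_rng(seed)
    t = np.arange(n) / fps
    y = np.zeros(n)
    for pk in peak_times:
        y += amp * np.exp(-0.5 * ((t - pk) / 0.3) ** 2)
    y += noise * rng.normal(size=n)
    return CalciumTrace(cell, seg, y, fps)


# -- Fisher z -----------------------------------------------------------------

def test_fisher_z_closed_forms():
    # tanh(atanh(0.8)/2) = tanh(ln sqrt(3)) = 0.5 exactly
    assert cs.fisher_z_mean([0.8, 0.0]) == pytest.approx(0.5, abs=1e-12)
    assert cs.fisher_z_mean([0.5, 0.5]) == pytest.approx(0.5, abs=1e-12)
    assert cs.fisher_z_mean([0.7, -0.7]) == pytest.approx(0.0, abs=1e-12)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.lists(st.floats(-0.999, 0.999), min_size=1, max_size=10))
def test_fisher_z_mean_within_input_range(rs):
    m = cs.fisher_z_mean(rs)
    assert min(rs) - 1e-12 <= m <= max(rs) + 1e-12


def test_fisher_z_empty_rejected():
    with pytest.raises(InputError):
        cs.fisher_z_mean([])


# -- lagged cross-correlation -------------------------------------------------

def test_xcorr_self_peaks_at_zero():
    tr = burst_trace([5.0, 15.0, 25.0])
    lags, rs = cs.lagged_xcorr(tr, tr, max_lag_s=3.0)
    i0 = np.argmin(np.abs(lags))
    assert rs[i0] == pytest.approx(1.0)
    assert np.nanargmax(rs) == i0


@pytest.mark.parametrize("k", [3, 7, -5])
def test_xcorr_shifted_copy_peaks_at_shift(k):
    tr = burst_trace([5.0, 15.0, 25.0], n=400)
    shifted = CalciumTrace("X", "A5", np.roll(tr.dff, k), FPS)
    lags, rs = cs.lagged_xcorr(tr, shifted, max_lag_s=2.0)
    assert lags[np.nanargmax(rs)] == pytest.approx(k / FPS, abs=1e-9)


def test_xcorr_antisymmetric_under_swap():
    a = burst_trace([5.0, 16.0], seed=1, noise=0.05)
    b = burst_trace([6.0, 15.0], seed=2, noise=0.05, seg="A5")
    lags_ab, r_ab = cs.lagged_xcorr(a, b, 1.5)
    lags_ba, r_ba = cs.lagged_xcorr(b, a, 1.5)
    np.testing.assert_allclose(r_ab, r_ba[::-1], atol=1e-9)


def test_xcorr_white_noise_near_zero():
    worst = 0.0
    n = 600
    for seed in range(20):
        rng = np.random.default_rng(seed)
        a = CalciumTrace("X", "A4", rng.normal(size=n), FPS)
        b = CalciumTrace("X", "A5", rng.normal(size=n), FPS)
        _, rs = cs.lagged_xcorr(a, b, 1.0)
        worst = max(worst, np.nanmax(np.abs(rs)))
    # the bound is on the maximum over ~400 lag/seed combinations, so allow
    # the expected extreme of that many null correlations
    assert worst <= 4.0 / np.sqrt(n - 10)


# -- alignment ----------------------------------------------------------------

def make_cycle_set():
    peaks_a4 = [5.0, 15.0, 25.0]
    peaks_a2 = [8.0, 18.0, 28.0]
    mid = [6.5, 16.5, 26.5]
    return [burst_trace(peaks_a4, cell="nSyb", seg="A4"),
            burst_trace(peaks_a2, cell="nSyb", seg="A2"),
            burst_trace(mid, cell="nSyb", seg="A3", amp=0.7)]


def test_alignment_normalizes_to_unit_range_and_anchors():
    aligned = cs.normalize_and_align(make_cycle_set(), "nSyb_A4", "nSyb_A2")
    assert aligned.n_cycles == 3
    for label, (lo, hi) in aligned.normalization.items():
        assert hi > lo
    # anchor peaks at normalized 0 and 1
    mean_a4 = aligned.mean("nSyb_A4")
    mean_a2 = aligned.mean("nSyb_A2")
    assert aligned.grid[np.argmax(mean_a4)] == pytest.approx(0.0, abs=0.02)
    assert aligned.grid[np.argmax(mean_a2)] == pytest.approx(1.0, abs=0.02)


def test_alignment_maps_known_event_to_rescaled_time():
    aligned = cs.normalize_and_align(make_cycle_set(), "nSyb_A4", "nSyb_A2")
    # A3 peaks at 6.5 between anchors 5.0 and 8.0 -> normalized 0.5
    mean_a3 = aligned.mean("nSyb_A3")
    assert aligned.grid[np.argmax(mean_a3)] == pytest.approx(0.5, abs=0.05)


def test_alignment_missing_anchor_is_an_error():
    with pytest.raises(InputError):
        cs.normalize_and_align(make_cycle_set(), "nSyb_A4", "nSyb_A9")


# -- intersegmental lag -------------------------------------------------------

def test_identical_traces_have_zero_lag():
    tr = burst_trace([5.0, 15.0, 25.0])
    copies = [CalciumTrace("A31c", seg, tr.dff, FPS)
              for seg in ("A2", "A4", "A7")]
    out = cs.intersegmental_lag([copies], reference="A7")
    assert all(lag == 0.0 for lag in out["lag"].values())


def test_wave_profile_lags_match_configuration(wave_calcium_profile):
    """nSyb set with a 0.4 s/segment lag: estimated lag of segment Aj vs the
    A7 reference is 0.4 (7 - j) s within one frame."""
    traces, _ = simulate_calcium(wave_calcium_profile, seed=3)
    out = cs.intersegmental_lag([traces], reference="A7", max_lag_s=2.5)
    for seg, lag in out["lag"].items():
        expected = 0.4 * (7 - int(seg[1]))
        assert lag == pytest.approx(expected, abs=1.0 / FPS + 1e-9)


def test_synchronous_profile_lags_near_zero(sync_calcium_profile):
    """A26f/A31c-style synchronous sets: |lag| at most one frame in every
    segment (the near-zero intersegmental lag of the interwave phase)."""
    traces, _ = simulate_calcium(sync_calcium_profile, seed=5)
    a31c = [tr for tr in traces if tr.cell_type == "A31c"]
    out = cs.intersegmental_lag([a31c], reference="A7")
    for lag in out["lag"].values():
        assert abs(lag) <= 1.0 / FPS + 1e-9


def test_generator_peak_times_match_truth(wave_calcium_profile):
    traces, truth = simulate_calcium(wave_calcium_profile, seed=9)
    for tr in traces:
        got = cs.detect_peaks(tr, min_interval_s=2.0)
        want = truth[tr.label]
        assert got.size == want.size
        np.testing.assert_allclose(got, want, atol=1.0 / FPS + 1e-9)


# -- relative peak times ------------------------------------------------------

def test_relative_peak_times_examples():
    bracket = burst_trace([5.0, 15.0])
    target_mid = burst_trace([10.0])
    np.testing.assert_allclose(
        cs.relative_peak_times(target_mid, bracket), [0.5], atol=0.02)
    target_at_first = burst_trace([5.0])
    np.testing.assert_allclose(
        cs.relative_peak_times(target_at_first, bracket), [0.0], atol=0.02)


def test_alternation_profile_positions_inside_unit_interval(
        sync_calcium_profile):
    """A26f bursts fall strictly between consecutive A31c bursts."""
    traces, _ = simulate_calcium(sync_calcium_profile, seed=6)
    a31c = next(tr for tr in traces if tr.label == "A31c_A4")
    a26f = next(tr for tr in traces if tr.label == "A26f_A4")
    pos = cs.relative_peak_times(a26f, a31c, min_interval_s=2.0)
    assert pos.size >= 4
    assert np.all((pos > 0) & (pos < 1))
    np.testing.assert_allclose(pos, 0.5, atol=0.05)


def test_dff_helper():
    f = np.concatenate([np.full(90, 2.0), np.full(10, 4.0)])
    d = cs.dff_from_raw(f)
    assert d.min() == pytest.approx(0.0)
    assert d.max() == pytest.approx(1.0)
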