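"""Generator properties: determinism, ground-truth consistency, calibration."""

import numpy as np
import pytest

from larvacrawl.config import AnalysisConfig
from larvacrawl import kinematics
from larvacrawl.synthetic import (CalibrationProfile, ConfigError,
                                  calibrate_profile, load_profile,
                                  simulate_calcium, simulate_crawl_dataset,
                                  simulate_crawl_episode,
                                  simulate_muscle_traces,
                                  simulate_optogenetic_trials)


def test_zero_noise_duty_factor_exact(noise_free_profile):
    _, gt = simulate_crawl_episode(noise_free_profile, seed=1)
    np.testing.assert_allclose(gt.duty_factor, 0.25, atol=1e-12)
    np.testing.assert_allclose(gt.interwave_duration + gt.wave_duration,
                               gt.stride_duration, atol=1e-12)


def test_stride_count_matches_profile(noise_free_profile):
    for seed in (1, 9):
        _, gt = simulate_crawl_episode(noise_free_profile, seed)
        assert gt.n_strides == 5


def test_invalid_counts_rejected(noise_free_profile):
    with pytest.raises(ConfigError):
        CalibrationProfile(counts=dict(n_animals=0, episodes_per_animal=1,
                                       strides_per_episode=5))
    with pytest.raises(ConfigError):
        CalibrationProfile(counts=dict(n_animals=1, episodes_per_animal=1,
                                       strides_per_episode=0))


def test_seeded_determinism_crawl(noise_free_profile):
    p = noise_free_profile.copy()
    p.kinematics["interwave_noise_stride"] = 0.1
    a = simulate_crawl_dataset(p, 7)
    b = simulate_crawl_dataset(p, 7)
    for (ta, ga), (tb, gb) in zip(a, b):
        np.testing.assert_array_equal(ta.positions["head"],
                                      tb.positions["head"])
        np.testing.assert_array_equal(ga.t_unhook, gb.t_unhook)
    c = simulate_crawl_dataset(p, 8)
    assert not np.array_equal(a[0][1].t_unhook, c[0][1].t_unhook)


def test_ground_truth_self_consistent_on_noise_free_data(noise_free_profile):
    """Re-deriving the phase durations from the emitted landmark positions
    reproduces the ground truth up to frame quantization."""
    frame = 1.0 / 30.0
    cfg = AnalysisConfig(frame_rate_hz=30.0, segment_length_mm=4.0 / 11.0)
    track, gt = simulate_crawl_episode(noise_free_profile, seed=11)
    table = kinematics.analyze_track(track, cfg)
    assert len(table) == gt.n_strides
    got_iw = np.array([s.interwave_duration for s in table])
    got_wv = np.array([s.wave_duration for s in table])
    assert np.sqrt(np.mean((got_iw - gt.interwave_duration) ** 2)) <= frame
    assert np.sqrt(np.mean((got_wv - gt.wave_duration) ** 2)) <= frame
    got_len = np.array([s.stride_length for s in table])
    np.testing.assert_allclose(got_len, gt.stride_length, atol=0.02)


def test_muscle_intersegmental_lag_read_off_event_times(
        noise_free_muscle_profile):
    """Configured 0.05 s/segment lag: VL4 onsets in A7 and A5 differ by
    exactly 0.10 s in the ground-truth event times."""
    track, gt = simulate_crawl_episode(noise_free_muscle_profile, seed=2)
    simulate_muscle_traces(noise_free_muscle_profile, gt, seed=2)
    onsets = {}
    w0 = gt.t_wave_onset[0]
    for muscle, seg, on, off, amp in gt.contraction_events:
        # wave-phase events only (A7 also contracts during the interwave)
        if muscle == "VL4" and seg in ("A5", "A7") and on >= w0 - 1e-9:
            onsets.setdefault(seg, []).append(on)
    a7 = min(onsets["A7"])
    a5 = min(onsets["A5"])
    assert a5 - a7 == pytest.approx(0.10, abs=1e-9)


def test_lt2_duration_equals_interwave_at_unit_coupling(
        noise_free_muscle_profile):
    _, gt = simulate_crawl_episode(noise_free_muscle_profile, seed=3)
    np.testing.assert_allclose(gt.lt2_duration, gt.interwave_duration,
                               atol=1e-12)


def test_calcium_zero_noise_traces_identical_up_to_amplitude(
        sync_calcium_profile):
    p = sync_calcium_profile.copy()
    p.calcium["noise_sd"] = 0.0
    for roi in p.calcium["rois"]:
        roi["segment_amp_jitter"] = 0.0
    traces, _ = simulate_calcium(p, seed=1)
    a26f = [tr for tr in traces if tr.cell_type == "A26f"]
    ref = a26f[0].dff
    for tr in a26f[1:]:
        ratio = tr.dff[ref > 0.1 * ref.max()] / ref[ref > 0.1 * ref.max()]
        np.testing.assert_allclose(ratio, ratio[0], atol=1e-9)


def test_calcium_peak_time_lags(wave_calcium_profile):
    """Configured 0.4 s nSyb lag: adjacent-segment ground-truth peak-time
    differences equal 0.4 s."""
    _, truth = simulate_calcium(wave_calcium_profile, seed=4)
    for j in range(2, 8):
        d = truth[f"nSyb_A{j}"] - truth[f"nSyb_A{j + 1}"]
        np.testing.assert_allclose(d, 0.4, atol=1e-9)


def test_opto_determinism_and_icc():
    prof = CalibrationProfile(
        name="icc",
        counts=dict(n_animals=2, episodes_per_animal=1, strides_per_episode=1),
        opto=dict(n_animals=200, trials_per_animal=20, baseline=0.0,
                  animal_sd=1.0, trial_sd=1.0, effect=0.0))
    a1, b1, _ = simulate_optogenetic_trials(prof, seed=5)
    a2, _, _ = simulate_optogenetic_trials(prof, seed=5)
    for x, y in zip(a1.animals, a2.animals):
        np.testing.assert_array_equal(x, y)
    # empirical intraclass correlation ~ sigma_a^2/(sigma_a^2 + sigma_w^2)
    vals = np.stack(a1.animals)
    between = vals.mean(axis=1).var(ddof=1) - vals.var(axis=1, ddof=1).mean() / 20
    within = vals.var(axis=1, ddof=1).mean()
    icc = between / (between + within)
    assert icc == pytest.approx(0.5, abs=0.05)


def test_opto_null_group_difference_centered_on_zero():
    prof = CalibrationProfile(
        name="null",
        counts=dict(n_animals=2, episodes_per_animal=1, strides_per_episode=1),
        opto=dict(n_animals=30, trials_per_animal=10, baseline=0.0,
                  animal_sd=1.0, trial_sd=1.0, effect=0.0))
    diffs = []
    for seed in range(30):
        a, b, _ = simulate_optogenetic_trials(prof, seed)
        diffs.append(np.mean([x.mean() for x in a.animals])
                     - np.mean([x.mean() for x in b.animals]))
    assert np.mean(diffs) == pytest.approx(0.0, abs=0.1)


def test_calibrate_profile_drives_noise_to_match_target(
        noise_free_muscle_profile):
    """Calibrating the contraction-noise sd against a correlation target:
    the secant solver recovers the noise level that yields the requested
    r between ground-truth contraction and interwave durations."""
    base = noise_free_muscle_profile.copy()
    base.counts = dict(n_animals=6, episodes_per_animal=2,
                       strides_per_episode=6)
    base.speed = dict(law="stratified_uniform", v_min=0.5, v_max=1.1,
                      episode_delta=0.05)
    base.kinematics["interwave_noise_stride"] = 0.15
    base.kinematics["moment_matching"] = True
    base.muscles["lt2"]["noise_stride"] = 0.02

    def stat(profile, seed):
        gts = [gt for _, gt in simulate_crawl_dataset(profile, seed)]
        C = np.concatenate([g.lt2_duration for g in gts])
        Ti = np.concatenate([g.interwave_duration for g in gts])
        return {"r": float(np.corrcoef(C, Ti)[0, 1])}

    out = calibrate_profile({"r": 0.85}, base, stat,
                            {"r": "muscles.lt2.noise_stride"},
                            seeds=(1, 2, 3), tol=0.02)
    vals = [stat(out, s)["r"] for s in (1, 2, 3)]
    assert np.mean(vals) == pytest.approx(0.85, abs=0.02)
    # limit case: a perfect-correlation target drives the noise sd to ~0
    out2 = calibrate_profile({"r": 0.999}, base, stat,
                             {"r": "muscles.lt2.noise_stride"},
                             seeds=(1, 2), tol=0.005)
    assert out2.get_param("muscles.lt2.noise_stride") < 0.02


def test_packaged_profiles_load():
    for name in ("fig1_topview", "fig1_sideview", "fig2_calcium",
                 "fig4_calcium", "opto_null", "opto_effect"):
        prof = load_profile(name)
        assert prof.name == name
    with pytest.raises(ConfigError):
        load_profile("no_such_profile")


def test_emergent_speeds_span_observed_range():
    """Calibrated top-view profile: per-episode crawling speeds emerge
    within the observed 0.35-1.23 mm/s range."""
    prof = load_profile("fig1_topview")
    speeds = [gt.episode_speed for _, gt in simulate_crawl_dataset(prof, 1)]
    assert min(speeds) >= 0.35
    assert max(speeds) <= 1.23
    assert max(speeds) - min(speeds) > 0.6   # spans most of the range
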