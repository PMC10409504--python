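import numpy as np
import pytest

from larvacrawl.synthetic import CalibrationProfile


@pytest.fixture
def noise_free_profile():
    """Deterministic episode: interwave 0.25 s, wave 0.75 s, 5 strides."""
    return CalibrationProfile(
        name="noise_free",
        counts=dict(n_animals=1, episodes_per_animal=1, strides_per_episode=5),
        speed=dict(law="stratified_uniform", v_min=0.799, v_max=0.801,
                   episode_delta=0.0),
        kinematics=dict(
            model="phase",
            interwave_intercept=0.25, interwave_speed_slope=0.0,
            interwave_noise_episode=0.0, interwave_noise_stride=0.0,
            interwave_floor=0.0,
            wave_intercept=0.75, wave_speed_slope=0.0,
            wave_interwave_coupling=0.0, wave_noise_stride=0.0,
            wave_noise_episode=0.0, wave_floor=0.3,
            length_noise=0.0, moment_matching=False),
        geometry=dict(frame_rate_hz=30.0, body_length_mm=4.0,
                      lead_in_s=1.2, lead_out_s=1.0,
                      head_advance_frac=0.6, tail_advance_frac=0.8,
                      landmark_noise_mm=0.0),
    )


@pytest.fixture
def noise_free_muscle_profile(noise_free_profile):
    """Noise-free side-view episode whose LT2 contraction duration equals the
    interwave duration by construction (unit coupling, zero noise)."""
    p = noise_free_profile.copy()
    p.muscles = dict(
        trace_noise_mm=0.0,
        lt2=dict(segments=["A2", "A3", "A4", "A5", "A6", "A7"],
                 rest_length_mm=0.4, duration_coupling=1.0,
                 wave_noise_coupling=0.0, noise_episode=0.0, noise_stride=0.0,
                 duration_floor=0.02, amp_intercept=0.3, amp_slope=0.0,
                 amp_noise=0.0, amp_range=[0.08, 0.6], segment_jitter=0.0),
        longitudinal=dict(muscles=["VL4", "DO1"],
                          segments=["A2", "A3", "A4", "A5", "A6", "A7"],
                          rest_length_mm=1.0, intersegmental_lag_s=0.05,
                          duration_frac_of_wave=0.45, amplitude=0.3,
                          posterior_interwave_segments=["A6", "A7"]),
    )
    return p


@pytest.fixture
def sync_calcium_profile():
    """A31c/A26f-style synchronous bursts, A26f midway between A31c bursts."""
    return CalibrationProfile(
        name="sync_calcium",
        counts=dict(n_animals=1, episodes_per_animal=1, strides_per_episode=1),
        calcium=dict(frame_rate_hz=10.0, cycle_period_s=10.0, n_cycles=6,
                     lead_s=3.0, rise_s=0.2, decay_s=0.8, noise_sd=0.02,
                     rois=[
                         dict(cell_type="A31c",
                              segments=["A2", "A3", "A4", "A5", "A6", "A7"],
                              intersegmental_lag_s=0.0, amplitude=1.0,
                              segment_amp_jitter=0.1),
                         dict(cell_type="A26f", segments=["A3", "A4", "A5"],
                              intersegmental_lag_s=0.0, cycle_offset_frac=0.5,
                              amplitude=0.9, segment_amp_jitter=0.1),
                     ]),
    )


@pytest.fixture
def wave_calcium_profile():
    """nSyb-style wave with a configured 0.4 s intersegmental lag."""
    return CalibrationProfile(
        name="wave_calcium",
        counts=dict(n_animals=1, episodes_per_animal=1, strides_per_episode=1),
        calcium=dict(frame_rate_hz=10.0, cycle_period_s=10.0, n_cycles=6,
                     lead_s=3.0, rise_s=0.2, decay_s=0.8, noise_sd=0.02,
                     rois=[
                         dict(cell_type="nSyb",
                              segments=["A2", "A3", "A4", "A5", "A6", "A7", "A8"],
                              intersegmental_lag_s=0.4, wave_delay_s=2.0,
                              amplitude=1.0, segment_amp_jitter=0.1),
                     ]),
    )


@pytest.fixture
def opto_profile():
    return CalibrationProfile(
        name="opto",
        counts=dict(n_animals=8, episodes_per_animal=1, strides_per_episode=1),
        opto=dict(n_animals=8, trials_per_animal=5, baseline=0.0,
                  animal_sd=1.0, trial_sd=1.0, effect=0.0),
    )
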