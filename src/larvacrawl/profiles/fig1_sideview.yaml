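# Side-view muscle-imaging study conditions: 9 larvae x 2 episodes x 4
# strides (~72 strides), calibrated so that event detection on the LT2
# traces reproduces the printed contraction-duration correlations.
name: fig1_sideview
counts:
  n_animals: 9
  episodes_per_animal: 2
  strides_per_episode: 4
speed:
  law: stratified_uniform
  v_min: 0.40494
  v_max: 1.17142
  episode_delta: 0.06
kinematics:
  model: phase
  interwave_intercept: 0.84003
  interwave_speed_slope: -0.37752374166660385
  interwave_noise_episode: 0.05354043066710696
  interwave_noise_stride: 0.20735637011507368
  interwave_floor: 0.12
  wave_intercept: 1.08704
  wave_speed_slope: -0.3265229282464216
  wave_interwave_coupling: -0.09127751767201073
  wave_noise_stride: 0.07877114559396162
  wave_noise_episode: 0.045369547688479686
  wave_floor: 0.3
  length_noise: 0.05
  moment_matching: true
geometry:
  frame_rate_hz: 30.0
  body_length_mm: 4.0
  lead_in_s: 1.2
  lead_out_s: 1.0
  head_advance_frac: 0.6
  tail_advance_frac: 0.8
  landmark_noise_mm: 0.004
muscles:
  trace_noise_mm: 0.002
  lt2:
    segments:
    - A2
    - A3
    - A4
    - A5
    - A6
    - A7
    rest_length_mm: 0.4
    duration_coupling: 0.8
    wave_noise_coupling: 0.028592629382278457
    noise_episode: 0.08301669829792022
    noise_stride: 0.025690263909857246
    duration_floor: 0.1
    amp_intercept: 0.12
    amp_slope: 0.35
    amp_noise: 0.04
    amp_range:
    - 0.08
    - 0.6
    segment_jitter: 0.02
  longitudinal:
    muscles:
    - VL4
    - DO1
    segments:
    - A2
    - A3
    - A4
    - A5
    - A6
    - A7
    rest_length_mm: 1.0
    intersegmental_lag_s: 0.08
    duration_frac_of_wave: 0.45
    amplitude: 0.3
    posterior_interwave_segments:
    - A6
    - A7
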