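# Top-view crawling study conditions: 18 larvae x 3 episodes x 5 strides
# (~270 strides), calibrated so the full pipeline reproduces the printed
# duty-factor regression and phase/speed/stride-duration correlations.
name: fig1_topview
counts:
  n_animals: 18
  episodes_per_animal: 3
  strides_per_episode: 5
speed:
  law: stratified_uniform
  v_min: 0.40566398638789164
  v_max: 1.1707658542962578
  episode_delta: 0.05
kinematics:
  model: duty
  duty_intercept: 0.6244509441771723
  duty_speed_slope: -0.5605346595334401
  duty_noise_episode: 0.0027488631753040467
  duty_noise_stride: 0.09597904142589901
  duty_noise_speed_exponent: 1.6864911475817574
  duration_intercept: 2.251580807101957
  duration_speed_slope: -1.3325506604071304
  duration_duty_coupling: 0.8359143885292507
  duration_noise_stride: 0.027760139871678857
  duration_noise_episode: 0.08033330231930566
  duration_floor: 0.45
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
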