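# Fictive-locomotion calcium imaging of the GABAergic interneurons: A31c
# and A26f burst synchronously across segments between fictive waves; the
# A26f burst falls midway between two consecutive A31c bursts (bookended).
name: fig4_calcium
counts: {n_animals: 1, episodes_per_animal: 1, strides_per_episode: 1}
speed: {law: stratified_uniform, v_min: 0.5, v_max: 1.0, episode_delta: 0.0}
geometry:
  frame_rate_hz: 30.0
  body_length_mm: 4.0
  lead_in_s: 1.2
  lead_out_s: 1.0
  head_advance_frac: 0.6
  tail_advance_frac: 0.8
  landmark_noise_mm: 0.0
calcium:
  frame_rate_hz: 10.0
  cycle_period_s: 10.0
  n_cycles: 6
  lead_s: 3.0
  rise_s: 0.2
  decay_s: 0.8
  noise_sd: 0.02
  rois:
    - cell_type: A31c
      segments: [A2, A3, A4, A5, A6, A7]
      intersegmental_lag_s: 0.0
      wave_delay_s: 0.0
      amplitude: 1.0
      segment_amp_jitter: 0.1
    - cell_type: A26f
      segments: [A3, A4, A5]
      intersegmental_lag_s: 0.0
      cycle_offset_frac: 0.5
      amplitude: 0.9
      segment_amp_jitter: 0.1
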