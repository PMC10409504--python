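# Optogenetic trial structure with a strong condition effect (e.g. a
# change in the normalized minimum LT2 length under illumination).
name: opto_effect
counts: {n_animals: 8, episodes_per_animal: 1, strides_per_episode: 1}
speed: {law: stratified_uniform, v_min: 0.5, v_max: 1.0, episode_delta: 0.0}
geometry:
  frame_rate_hz: 30.0
  body_length_mm: 4.0
  lead_in_s: 1.2
  lead_out_s: 1.0
  head_advance_frac: 0.6
  tail_advance_frac: 0.8
  landmark_noise_mm: 0.0
opto:
  n_animals: 8
  trials_per_animal: 5
  baseline: 0.0
  animal_sd: 0.5
  trial_sd: 0.5
  effect: 5.0
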