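{
  "duty_vs_speed_r2": 0.5490735718688247,
  "duty_vs_speed_slope": -0.47744401639406536,
  "interwave_vs_speed_r": -0.720416611291242,
  "interwave_vs_stride_r": 0.8424583182620122,
  "n_episodes": 54,
  "n_strides": 270,
  "speed_max": 1.1914224824069852,
  "speed_min": 0.3782447942726804,
  "wave_vs_speed_r": -0.6122616591271034,
  "wave_vs_stride_r": 0.5548283706708342
}
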