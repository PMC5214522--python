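{
  "wildtype": {
    "base_speed_mm_s": 10.0,
    "reversal_rate_hz": 0.1,
    "g_max": 16.0,
    "a_incr": 0.5,
    "tau_a_s": 60.0,
    "a_opt": 1.0,
    "a_sigma": 0.6,
    "f_peak_hz": 30.0,
    "f_sigma": 0.8,
    "motion_speed_boost": 1.2
  },
  "null": {
    "base_speed_mm_s": 10.0,
    "reversal_rate_hz": 0.1,
    "g_max": 0.0,
    "a_incr": 0.5,
    "tau_a_s": 60.0,
    "a_opt": 1.0,
    "a_sigma": 0.6,
    "f_peak_hz": 30.0,
    "f_sigma": 0.8,
    "motion_speed_boost": 1.0
  },
  "hyperactive-low-gain": {
    "base_speed_mm_s": 10.0,
    "reversal_rate_hz": 0.1,
    "g_max": 1.5,
    "a_incr": 0.5,
    "tau_a_s": 60.0,
    "a_opt": 1.0,
    "a_sigma": 0.6,
    "f_peak_hz": 30.0,
    "f_sigma": 0.8,
    "motion_speed_boost": 1.8
  }
}
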