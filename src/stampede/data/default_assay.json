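{
  "startle": {"n_events": 2, "event_s": 1.0, "gap_s": 1.0},
  "motion": {"rate_hz": 25.0, "duration_s": 60.0},
  "rest_s": 60.0,
  "panel": {"n_rows": 16, "n_cols": 32, "stripe_cols": 2},
  "preset": "wildtype",
  "n_flies": 1,
  "fps": 25.0,
  "seed": 0
}
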