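{
  "stroke_rate_by_chads2": [0.019, 0.028, 0.040, 0.059, 0.085, 0.125, 0.182],
  "warfarin_bleed_rate_by_hemorrhages": [0.019, 0.025, 0.053, 0.084, 0.104, 0.123],
  "warfarin_bleed_score_cap": 5,
  "baseline_bleed_rate": {
    "age_band_lower_bounds": [0, 60, 70, 80],
    "no_prior_bleed": [0.0012, 0.005, 0.012, 0.025],
    "prior_bleed": [0.010, 0.015, 0.030, 0.060]
  },
  "aspirin_stroke_rrr": 0.21,
  "warfarin_stroke_rrr": 0.67,
  "aspirin_bleed_rr": 2.0,
  "default_horizon_years": 5.0
}
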