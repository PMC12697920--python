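{
  "version": "1.0",
  "notes": "Weighted-window sleep-wake scoring algorithms for 30-second wrist actigraphy activity counts. Offsets are epoch positions relative to the scored epoch; score = scale * sum(weight * count[offset]). Values follow the original algorithm publications; three typographically ambiguous entries (Cole-Kripke centre weight 121, Kripke 2010 trailing weight 0.0100, Philips trailing offset +4) are editorial readings and can be overridden here without code changes.",
  "algorithms": {
    "cole_kripke": {
      "kind": "weighted_window",
      "offsets": [-4, -3, -2, -1, 0, 1, 2],
      "weights": [50, 30, 14, 28, 121, 8, 50],
      "scale": 0.0001,
      "threshold": 1.0,
      "decision": "sleep_if_score_lt_threshold"
    },
    "ucsd": {
      "kind": "weighted_window",
      "offsets": [-4, -3, -2, -1, 0, 1, 2],
      "weights": [0.010, 0.015, 0.028, 0.031, 0.085, 0.015, 0.010],
      "scale": 0.05,
      "threshold": 1.0,
      "decision": "sleep_if_score_lt_threshold"
    },
    "kripke2010": {
      "kind": "weighted_window",
      "offsets": [-10, -9, -8, -7, -6, -5, -4, -3, -2, -1, 0, 1, 2],
      "weights": [0.0064, 0.0074, 0.0112, 0.0112, 0.0118, 0.0118, 0.0128, 0.0188, 0.0280, 0.0664, 0.0300, 0.0112, 0.0100],
      "scale": 0.30,
      "threshold": 1.0,
      "decision": "sleep_if_score_lt_threshold"
    },
    "philips": {
      "kind": "weighted_window",
      "offsets": [-4, -3, -2, -1, 0, 1, 2, 3, 4],
      "weights": [0.04, 0.04, 0.2, 0.2, 2.0, 0.2, 0.2, 0.04, 0.04],
      "scale": 1.0,
      "threshold": 40.0,
      "thresholds": [20.0, 40.0, 80.0],
      "decision": "sleep_if_score_le_threshold"
    },
    "sadeh": {
      "kind": "sadeh",
      "coefficients": {"intercept": 7.601, "avg": 0.065, "nats": 1.08, "sd": 0.056, "lg": 0.703},
      "clip": 300.0,
      "log_offset": 1.0,
      "threshold": 0.0,
      "decision": "sleep_if_score_ge_threshold"
    }
  }
}
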