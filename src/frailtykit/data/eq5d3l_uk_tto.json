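{
  "name": "uk_tto",
  "description": "UK time-trade-off value set for EQ-5D-3L (MVH study, Dolan 1997 N3 model). Utility = 1 - constant (if any dimension above level 1) - per-dimension level decrements - n3 term (if any dimension at level 3).",
  "model": {
    "constant": 0.081,
    "n3": 0.269,
    "decrements": {
      "mobility": [0.069, 0.314],
      "self_care": [0.104, 0.214],
      "usual_activities": [0.036, 0.094],
      "pain_discomfort": [0.123, 0.386],
      "anxiety_depression": [0.071, 0.236]
    }
  }
}
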