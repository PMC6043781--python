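[
  {
    "model_name": "depth-05-generic",
    "diameter_mm": 0.8,
    "tip_offset_mm": 0.0,
    "segments": [
      {"n_contacts": 5, "contact_length_mm": 2.0, "gap_after_mm": 1.5}
    ]
  },
  {
    "model_name": "depth-10-generic",
    "diameter_mm": 0.8,
    "tip_offset_mm": 0.0,
    "segments": [
      {"n_contacts": 10, "contact_length_mm": 2.0, "gap_after_mm": 1.5}
    ]
  },
  {
    "model_name": "depth-12-generic",
    "diameter_mm": 0.8,
    "tip_offset_mm": 0.0,
    "segments": [
      {"n_contacts": 12, "contact_length_mm": 2.0, "gap_after_mm": 1.5}
    ]
  },
  {
    "model_name": "depth-15-generic",
    "diameter_mm": 0.8,
    "tip_offset_mm": 0.0,
    "segments": [
      {"n_contacts": 15, "contact_length_mm": 2.0, "gap_after_mm": 1.5}
    ]
  },
  {
    "model_name": "depth-18-generic",
    "diameter_mm": 0.8,
    "tip_offset_mm": 0.0,
    "segments": [
      {"n_contacts": 18, "contact_length_mm": 2.0, "gap_after_mm": 1.5}
    ]
  },
  {
    "model_name": "depth-15-grouped-3x5",
    "diameter_mm": 0.8,
    "tip_offset_mm": 0.0,
    "segments": [
      {"n_contacts": 5, "contact_length_mm": 2.0, "gap_after_mm": 1.5},
      {"n_contacts": 5, "contact_length_mm": 2.0, "gap_after_mm": 1.5},
      {"n_contacts": 5, "contact_length_mm": 2.0, "gap_after_mm": 1.5}
    ]
  },
  {
    "model_name": "depth-10-grouped-2x5-wide",
    "diameter_mm": 0.8,
    "tip_offset_mm": 0.0,
    "segments": [
      {"n_contacts": 4, "contact_length_mm": 2.0, "gap_after_mm": 1.5},
      {"n_contacts": 1, "contact_length_mm": 2.0, "gap_after_mm": 8.0},
      {"n_contacts": 5, "contact_length_mm": 2.0, "gap_after_mm": 1.5}
    ]
  }
]
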