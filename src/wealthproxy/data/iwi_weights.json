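{
  "schema_version": 1,
  "description": "International Wealth Index weights: constant + per-item weights for the seven consumer durables, electricity, and the three-level housing-quality items. Minimum configuration scores 0, maximum 100 (after clamping the rounding residue).",
  "constant": 25.00447,
  "boolean_weights": {
    "tv": 8.612657,
    "refrigerator": 8.429076,
    "phone": 7.127699,
    "car": 4.651382,
    "bicycle": 1.84686,
    "cheap_utensils": 4.118394,
    "expensive_utensils": 6.507283,
    "electricity": 8.056664
  },
  "categorical_weights": {
    "floor_quality": {"low": -7.558471, "medium": 1.227531, "high": 6.107428},
    "toilet_quality": {"low": -7.439841, "medium": -1.090393, "high": 8.140637},
    "rooms_category": {"low": -3.699681, "medium": 0.38405, "high": 3.445009},
    "water_quality": {"low": -6.306477, "medium": -2.302023, "high": 7.952443}
  }
}
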