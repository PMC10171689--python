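{
  "schema_version": 1,
  "description": "Recode rubric mapping raw survey vocabulary to the three ordered quality levels used by the wealth score. Raw strings are matched case-insensitively. This rubric follows the standard DHS-style quality groupings and is substitutable via configuration.",
  "floor_material": {
    "low": ["none", "earth", "sand", "mud", "dung", "clay"],
    "medium": ["wood planks", "palm", "bamboo", "raw wood", "cement", "brick"],
    "high": ["finished wood", "polished wood", "parquet", "vinyl", "linoleum", "ceramic tiles", "tiles", "mosaic", "marble", "carpet", "polished stone"]
  },
  "toilet_facility": {
    "low": ["none", "no facility", "bush", "field", "open defecation", "bucket", "hanging latrine"],
    "medium": ["pit latrine", "pit latrine with slab", "pit latrine without slab", "ventilated improved pit latrine", "composting toilet", "shared latrine"],
    "high": ["flush toilet", "flush to sewer", "flush to septic tank", "pour flush"]
  },
  "water_source": {
    "low": ["surface water", "river", "lake", "pond", "stream", "unprotected well", "unprotected spring"],
    "medium": ["public tap", "standpipe", "tube well", "borehole", "protected well", "protected spring", "rainwater", "tanker truck"],
    "high": ["piped into dwelling", "piped to yard", "piped water", "bottled water"]
  },
  "rooms": {"low_max": 1, "medium_max": 2}
}
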