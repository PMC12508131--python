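{
  "type": "object",
  "required": ["n_patients", "n_failed", "seeding_pattern_counts", "patients"],
  "properties": {
    "n_patients": {"type": "integer"},
    "n_failed": {"type": "integer"},
    "seeding_pattern_counts": {"type": "object"},
    "patients": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["patient", "scenario", "stages_completed"],
        "properties": {
          "patient": {"type": "string"},
          "scenario": {
            "type": "string",
            "enum": ["very_early_multiclonal", "early_sweep_chemo", "aml_dormant"]
          },
          "stages_completed": {"type": "array", "items": {"type": "string"}}
        }
      }
    }
  }
}
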