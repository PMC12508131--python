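{
  "type": "object",
  "required": ["patient", "scenario", "filter", "signatures", "clones", "mrd"],
  "properties": {
    "patient": {"type": "string"},
    "scenario": {
      "type": "string",
      "enum": ["very_early_multiclonal", "early_sweep_chemo", "aml_dormant"]
    },
    "filter": {
      "type": "object",
      "required": ["n_input", "n_kept", "n_dropped"],
      "properties": {
        "n_input": {"type": "integer"},
        "n_kept": {"type": "integer"},
        "n_dropped": {"type": "integer"}
      }
    },
    "signatures": {
      "type": "object",
      "required": ["exposures", "class_sums", "primary"],
      "properties": {
        "exposures": {"type": "object"},
        "class_sums": {"type": "object"},
        "n_diagnostic_snvs": {"type": "integer"},
        "n_relapse_specific_snvs": {"type": "integer"}
      }
    },
    "clones": {
      "type": "object",
      "required": ["n_clusters", "seeding_pattern", "branching"],
      "properties": {
        "n_clusters": {"type": "integer"},
        "seeding_pattern": {
          "type": "string",
          "enum": ["multiple_clones", "sweep_detected", "sweep_not_detected"]
        },
        "branching": {"type": "boolean"}
      }
    },
    "mrd": {
      "type": "object",
      "required": ["calls"],
      "properties": {
        "calls": {
          "type": "array",
          "items": {
            "type": "object",
            "required": ["day", "status", "gate"],
            "properties": {
              "day": {"type": "integer"},
              "status": {
                "type": "string",
                "enum": ["detected", "undetected", "rescued_detected", "invalid"]
              },
              "gate": {
                "type": "string",
                "enum": ["fusion_present", "fusion_absent_rescued", "fusion_absent_failed"]
              }
            }
          }
        }
      }
    }
  }
}
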