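{
  "type": "object",
  "required": ["version", "plate_id", "criteria", "polarities"],
  "properties": {
    "version": {"type": "string"},
    "seed": {"type": "integer", "nullable": true},
    "plate_id": {"type": "string"},
    "criteria": {
      "type": "object",
      "required": ["mass_tol", "sigma_max", "blank_factor", "replicate_rule"],
      "properties": {
        "mass_tol": {"type": "number"},
        "sigma_max": {"type": "number"},
        "blank_factor": {"type": "number"},
        "replicate_rule": {"type": "string"}
      }
    },
    "polarities": {
      "type": "object",
      "additionalValues": {
        "type": "object",
        "required": ["calibration", "matches", "detections"],
        "properties": {
          "reference_rsd_percent": {"type": "number", "nullable": true},
          "calibration": {
            "type": "object",
            "additionalValues": {
              "type": "object",
              "required": ["kind", "coefficients", "n_refs_used", "rms_residual"],
              "properties": {
                "kind": {"type": "string"},
                "coefficients": {"type": "array", "items": {"type": "number"}},
                "n_refs_used": {"type": "integer"},
                "rms_residual": {"type": "number"}
              }
            }
          },
          "matches": {
            "type": "array",
            "items": {
              "type": "object",
              "required": [
                "compound", "species", "polarity", "well_id", "theoretical_mz",
                "observed_mz", "mass_error_mda", "peak_height", "iso_fit_score",
                "blank_threshold", "passed_all"
              ]
            }
          },
          "detections": {
            "type": "array",
            "items": {
              "type": "object",
              "required": [
                "sample_id", "compound", "species", "polarity", "n_detected",
                "n_measured", "validated", "confidence_level"
              ]
            }
          }
        }
      }
    }
  }
}
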