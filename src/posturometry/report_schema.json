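{
  "$schema": "http://json-schema.org/draft-07/schema#",
  "$id": "posturometry-study-report",
  "version": "0.1.0",
  "title": "Screening-study report",
  "type": "object",
  "required": ["design", "seed", "version", "n_comparisons", "config", "table", "missingness"],
  "properties": {
    "design": {"enum": ["reliability", "construct_validity", "discriminative"]},
    "seed": {"type": "integer"},
    "version": {"type": "string"},
    "n_comparisons": {"type": "integer", "minimum": 0},
    "config": {"type": "object"},
    "table": {
      "type": "array",
      "minItems": 18,
      "maxItems": 18,
      "items": {
        "type": "object",
        "required": ["variable", "units"],
        "properties": {
          "variable": {"type": "string"},
          "units": {"type": "string"}
        }
      }
    },
    "missingness": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["variable", "n_missing"],
        "properties": {
          "variable": {"type": "string"},
          "n_missing": {"type": "integer", "minimum": 0}
        }
      }
    }
  }
}
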