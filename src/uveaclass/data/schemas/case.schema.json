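{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "$id": "uveaclass/case.schema.json",
  "title": "Case record document",
  "description": "One patient case as stored in cases.json ({\"cases\": [...], \"split\": {...}}). Vocabulary codes are validated against the registry by uveaclass.clinical_vocab.",
  "type": "object",
  "required": ["case_id", "anatomic_class"],
  "properties": {
    "case_id": {"type": "string"},
    "anatomic_class": {
      "enum": ["anterior", "intermediate", "posterior", "panuveitis", "infectious_post_pan"]
    },
    "course": {
      "enum": ["acute", "recurrent_acute", "chronic", "chronic_after_recurrent_acute", "unknown"]
    },
    "laterality": {
      "enum": ["unilateral", "alternating_unilateral", "bilateral", "unknown"]
    },
    "findings": {
      "type": "object",
      "additionalProperties": {
        "oneOf": [
          {"enum": ["present", "absent", "unknown"]},
          {
            "type": "object",
            "required": ["value"],
            "properties": {
              "value": {"enum": ["present", "absent", "unknown"]},
              "grade": {"type": "integer", "minimum": 0, "maximum": 4}
            }
          }
        ]
      }
    },
    "tests": {
      "type": "object",
      "additionalProperties": {"enum": ["positive", "negative", "unknown"]}
    },
    "true_label": {"type": "string"}
  }
}
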