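{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "$id": "uveaclass/ruleset.schema.json",
  "title": "Disease rule set",
  "description": "Named classification criteria: a boolean criteria expression tree over tri-state clinical atoms plus an ordered list of exclusion expressions. Validation is performed by uveaclass.criteria_engine (codes are additionally checked against the vocabulary registry).",
  "type": "object",
  "required": ["disease_id", "disease_name", "anatomic_class", "criteria"],
  "properties": {
    "disease_id": {"type": "string"},
    "disease_name": {"type": "string"},
    "anatomic_class": {
      "enum": ["anterior", "intermediate", "posterior", "panuveitis", "infectious_post_pan"]
    },
    "criteria": {"$ref": "#/$defs/expr"},
    "exclusions": {"type": "array", "items": {"$ref": "#/$defs/expr"}},
    "provenance": {"type": "string"}
  },
  "$defs": {
    "expr": {
      "type": "object",
      "oneOf": [
        {"required": ["and"], "properties": {"and": {"type": "array", "minItems": 1, "items": {"$ref": "#/$defs/expr"}}}},
        {"required": ["or"], "properties": {"or": {"type": "array", "minItems": 1, "items": {"$ref": "#/$defs/expr"}}}},
        {"required": ["not"], "properties": {"not": {"$ref": "#/$defs/expr"}}},
        {"required": ["finding", "is"], "properties": {"finding": {"type": "string"}, "is": {"enum": ["present", "absent"]}}},
        {"required": ["test", "is"], "properties": {"test": {"type": "string"}, "is": {"enum": ["positive", "negative"]}}},
        {"required": ["course_in"], "properties": {"course_in": {"type": "array", "items": {"type": "string"}}, "closed": {"type": "boolean"}}},
        {"required": ["laterality_in"], "properties": {"laterality_in": {"type": "array", "items": {"type": "string"}}, "closed": {"type": "boolean"}}},
        {"required": ["grade_lt"], "properties": {"grade_lt": {"type": "array", "prefixItems": [{"type": "string"}, {"type": "string"}]}}},
        {"required": ["grade_ge"], "properties": {"grade_ge": {"type": "array", "prefixItems": [{"type": "string"}, {"type": "integer"}]}}},
        {"required": ["finding_in"], "properties": {"finding_in": {"type": "array", "prefixItems": [{"type": "string"}, {"type": "array", "items": {"enum": ["present", "absent", "unknown"]}}]}}},
        {"required": ["test_in"], "properties": {"test_in": {"type": "array", "prefixItems": [{"type": "string"}, {"type": "array", "items": {"enum": ["positive", "negative", "unknown"]}}]}}},
        {"required": ["const"], "properties": {"const": {"type": "boolean"}}}
      ],
      "properties": {"label": {"type": "string"}}
    }
  }
}
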