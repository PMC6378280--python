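{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "Question bank",
  "description": "Schema of the YAML/JSON question-bank document accepted by slm.load_bank. Enforcement is performed by slm.validate_bank; this file documents the contract.",
  "type": "object",
  "required": ["questions"],
  "properties": {
    "version": {"type": "string"},
    "advice_interval": {"type": "integer", "minimum": 1, "default": 10},
    "questions": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["id", "group", "text"],
        "properties": {
          "id": {"type": "string"},
          "group": {
            "enum": ["affective", "genogram", "differentiation", "awareness", "interveneer"]
          },
          "subscale": {
            "description": "Sector for affective questions, pattern for differentiation questions, null otherwise.",
            "enum": [
              "affective_relational", "productivity", "sociocultural", "organic", "spiritual",
              "adaptation", "reaction", "creativity", null
            ]
          },
          "text": {"type": "string"},
          "response_kind": {"enum": ["likert", "structured"], "default": "likert"},
          "keying": {"enum": ["negative", "positive"], "default": "negative"},
          "score_map": {
            "description": "Option index (0..4) to non-negative inadequacy score; null selects the default keyed identity map. Must be null for structured questions and cover all five options for likert questions.",
            "type": ["object", "null"],
            "propertyNames": {"pattern": "^[0-4]$"},
            "additionalProperties": {"type": "number", "minimum": 0}
          }
        }
      }
    }
  }
}
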