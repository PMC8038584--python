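{
  "type": "object",
  "required": ["case_id", "validation", "approaches", "skipped", "compliance_pct"],
  "additionalProperties": false,
  "properties": {
    "case_id": {"type": "string"},
    "validation": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["code", "severity", "message"],
        "additionalProperties": false,
        "properties": {
          "code": {"type": "string"},
          "severity": {"type": "string", "enum": ["info", "warning", "reject"]},
          "message": {"type": "string"}
        }
      }
    },
    "approaches": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["name", "labels", "sentence", "evidence", "notes"],
        "additionalProperties": false,
        "properties": {
          "name": {
            "type": "string",
            "enum": ["physiological", "physiological_agc", "chemical", "chemical_agc"]
          },
          "labels": {"type": "array", "items": {"type": "string"}},
          "sentence": {"type": "string"},
          "evidence": {
            "type": "object",
            "additionalProperties": {"type": ["number", "string"]}
          },
          "notes": {"type": "array", "items": {"type": "string"}}
        }
      }
    },
    "skipped": {
      "type": "object",
      "additionalProperties": {"type": "string"}
    },
    "compliance_pct": {"type": ["number", "null"]}
  }
}
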