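{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "alignqc check report",
  "type": "object",
  "required": ["alignqc_version", "reports"],
  "properties": {
    "alignqc_version": {"type": "string"},
    "alignment": {"type": "string"},
    "ontology1": {"type": "string"},
    "ontology2": {"type": "string"},
    "reports": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["check_id", "status", "findings", "summary_counts"],
        "properties": {
          "check_id": {
            "type": "string",
            "enum": ["1", "2a", "2b", "3", "4", "5", "6", "7", "8", "9", "10"]
          },
          "status": {
            "type": "string",
            "enum": ["pass", "findings", "skipped", "not_applicable"]
          },
          "reason": {"type": "string"},
          "findings": {
            "type": "array",
            "items": {
              "type": "object",
              "required": ["check_id", "category", "entities"],
              "properties": {
                "check_id": {"type": "string"},
                "category": {"type": "string"},
                "entities": {"type": "array", "items": {"type": "string"}},
                "evidence": {"type": "object"}
              }
            }
          },
          "summary_counts": {
            "type": "object",
            "additionalProperties": {"type": "number"}
          }
        }
      }
    }
  }
}
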