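{
  "$comment": "Abbreviations JSON output: short form -> long form -> list of detection methods. One-sided entries are never stored; method lists are non-empty and duplicate-free.",
  "type": "object",
  "required": ["id", "key", "abbreviations"],
  "additionalProperties": false,
  "properties": {
    "id": {"type": "string"},
    "source": {"type": "string"},
    "key": {"type": "string"},
    "abbreviations": {
      "type": "object",
      "additionalProperties": {
        "type": "object",
        "additionalProperties": {
          "type": "array",
          "items": {
            "type": "string",
            "enum": ["fulltext_bracket", "abbreviations_section"]
          }
        }
      }
    }
  }
}
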