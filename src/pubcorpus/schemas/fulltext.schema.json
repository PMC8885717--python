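{
  "$comment": "BioC JSON full-text output. Passage offsets count Unicode code points from 0 over passage texts. Infons link section titles (section_title_1 = title, _2 = subtitle, ...) and IAO document-part annotations (iao_name_N / iao_id_N pairs; absent when no term could be assigned) directly to each passage.",
  "type": "object",
  "required": ["source", "date", "key", "documents"],
  "additionalProperties": false,
  "properties": {
    "source": {"type": "string"},
    "date": {"type": "string"},
    "key": {"type": "string"},
    "infons": {"type": "object"},
    "documents": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["id", "passages"],
        "additionalProperties": false,
        "properties": {
          "id": {"type": "string"},
          "infons": {"type": "object"},
          "passages": {
            "type": "array",
            "items": {
              "type": "object",
              "required": ["infons", "offset", "text"],
              "additionalProperties": false,
              "properties": {
                "infons": {
                  "type": "object",
                  "required": ["passage_type"],
                  "additionalProperties": false,
                  "patternProperties": {
                    "^(section_title|iao_name|iao_id)_[0-9]+$": {"type": "string"},
                    "^passage_type$": {"type": "string", "enum": ["text", "figure_caption"]}
                  }
                },
                "offset": {"type": "integer"},
                "text": {"type": "string"}
              }
            }
          }
        }
      }
    }
  }
}
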