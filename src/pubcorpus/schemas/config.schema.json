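{
  "$comment": "Source configuration: which HTML elements delimit headings, paragraphs and table parts for one publisher dialect. element_name is regex-full-matched against tag names; attribute constraint values are regex-searched against attribute values. Unknown keys are rejected by the loader.",
  "type": "object",
  "required": ["source_name", "selectors"],
  "additionalProperties": false,
  "properties": {
    "source_name": {"type": "string"},
    "contributors": {"type": "string"},
    "tables_mode": {"type": "string", "enum": ["inline", "linked", "both"]},
    "selectors": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["element_name", "scope"],
        "additionalProperties": false,
        "properties": {
          "element_name": {"type": "string"},
          "scope": {
            "type": "string",
            "enum": [
              "heading", "paragraph", "table_container", "table_title",
              "table_caption", "table_footer", "linked_table_marker"
            ]
          },
          "attribute_constraints": {
            "type": "array",
            "items": {
              "type": "array",
              "items": {"type": "string"}
            }
          }
        }
      }
    }
  }
}
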