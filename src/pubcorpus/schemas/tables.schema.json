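{
  "$comment": "Table JSON output: one object per article. Each table carries metadata passages labelled with the three table section types, pipe-joined column headers, and sectioned data rows. Cell identifiers: header cell T<table>.C<col>; data cell T<table>.S<section>.R<row>.C<col>, all 1-based, rows numbered within their section. Sub-tables are siblings with identifier <parent>_<k> and metadata copied from the parent.",
  "type": "object",
  "required": ["id", "key", "tables"],
  "additionalProperties": false,
  "properties": {
    "id": {"type": "string"},
    "source": {"type": "string"},
    "key": {"type": "string"},
    "tables": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["identifier", "metadata", "column_headers", "sections"],
        "additionalProperties": false,
        "properties": {
          "identifier": {"type": "string"},
          "metadata": {
            "type": "array",
            "items": {
              "type": "object",
              "required": ["section_type", "text"],
              "additionalProperties": false,
              "properties": {
                "section_type": {
                  "type": "string",
                  "enum": ["table title", "table caption", "table footer"]
                },
                "text": {"type": "string"}
              }
            }
          },
          "column_headers": {
            "type": "array",
            "items": {
              "type": "object",
              "required": ["cell_id", "text"],
              "additionalProperties": false,
              "properties": {
                "cell_id": {"type": "string"},
                "text": {"type": "string"}
              }
            }
          },
          "sections": {
            "type": "array",
            "items": {
              "type": "object",
              "required": ["section_name", "rows"],
              "additionalProperties": false,
              "properties": {
                "section_name": {"type": "string"},
                "rows": {
                  "type": "array",
                  "items": {
                    "type": "array",
                    "items": {
                      "type": "object",
                      "required": ["cell_id", "value"],
                      "additionalProperties": false,
                      "properties": {
                        "cell_id": {"type": "string"},
                        "value": {"type": ["number", "string"]}
                      }
                    }
                  }
                }
              }
            }
          }
        }
      }
    }
  }
}
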