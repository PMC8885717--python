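{
  "source_name": "generic-pmc-like",
  "contributors": "pubcorpus maintainers: starting point for PMC-style article pages; adjust selectors to the exact page structure before production use",
  "tables_mode": "inline",
  "selectors": [
    {"element_name": "h[2-4]", "scope": "heading"},
    {"element_name": "p", "scope": "paragraph"},
    {
      "element_name": "div",
      "attribute_constraints": [["class", "table-wrap"]],
      "scope": "table_container"
    },
    {
      "element_name": "h4",
      "attribute_constraints": [["class", "obj_head"]],
      "scope": "table_title"
    },
    {
      "element_name": "div",
      "attribute_constraints": [["class", "caption"]],
      "scope": "table_caption"
    },
    {
      "element_name": "div",
      "attribute_constraints": [["class", "tblwrap-foot"]],
      "scope": "table_footer"
    }
  ]
}
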