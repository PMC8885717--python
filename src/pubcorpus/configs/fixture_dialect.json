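{
  "source_name": "fixture-dialect",
  "selectors": [
    {
      "element_name": "h2",
      "attribute_constraints": [
        [
          "class",
          "section-title.*"
        ]
      ],
      "scope": "heading"
    },
    {
      "element_name": "h3",
      "attribute_constraints": [
        [
          "class",
          "section-sub"
        ]
      ],
      "scope": "heading"
    },
    {
      "element_name": "p",
      "attribute_constraints": [
        [
          "class",
          "paragraph"
        ]
      ],
      "scope": "paragraph"
    },
    {
      "element_name": "div",
      "attribute_constraints": [
        [
          "class",
          "table-box"
        ]
      ],
      "scope": "table_container"
    },
    {
      "element_name": "p",
      "attribute_constraints": [
        [
          "class",
          "table-title"
        ]
      ],
      "scope": "table_title"
    },
    {
      "element_name": "p",
      "attribute_constraints": [
        [
          "class",
          "table-caption"
        ]
      ],
      "scope": "table_caption"
    },
    {
      "element_name": "p",
      "attribute_constraints": [
        [
          "class",
          "table-footer"
        ]
      ],
      "scope": "table_footer"
    }
  ],
  "tables_mode": "both",
  "contributors": "generated fixture dialect"
}
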