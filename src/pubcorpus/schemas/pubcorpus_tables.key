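pubcorpus_tables.key — companion key for the table JSON output.

id                  article identifier
tables[].identifier table number from the title ("3"), positional otherwise;
                    sub-tables append "_k" ("3_1") and copy parent metadata
tables[].metadata   title/caption/footer passages, section_type one of
                    "table title", "table caption", "table footer"
tables[].column_headers
                    one entry per column; multi-row headers joined top-to-
                    bottom with "|", spanning headers replicated per column;
                    cell_id "T<table>.C<col>" (1-based)
tables[].sections   data rows grouped by super-row / index-column dividers;
                    rows before any divider form the unnamed section ""
rows[][].cell_id    "T<table>.S<section>.R<row>.C<col>" (1-based, rows
                    numbered within their section)
rows[][].value      JSON number for purely numeric cells (scientific notation
                    converted to exponential form); otherwise a string with
                    formatting removed except superscript, which is kept as
                    explicit <sup> markup
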