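pubcorpus_fulltext.key — companion key for the BioC full-text JSON output.

collection.source   tool that produced the file ("pubcorpus")
collection.date     production date (empty when omitted for reproducibility)
collection.key      this file
document.id         article identifier (filename stem; PMC id when present)
passage.offset      cumulative Unicode code-point count of preceding passage
                    texts, starting at 0
passage.text        markup-free passage text, UTF-8; link anchor text retained
passage.infons.section_title_N
                    section title (N=1), subtitle (N=2), and so on, linked
                    directly to the passage they govern
passage.infons.iao_name_N / iao_id_N
                    IAO document-part annotation(s) of the passage's section;
                    a passage may carry several terms or none
passage.infons.passage_type
                    "text" or "figure_caption" (captions stay in reading order)

Abbreviations-section passages are not present here; see the abbreviations
JSON. Table content is not present here; see the table JSON.
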