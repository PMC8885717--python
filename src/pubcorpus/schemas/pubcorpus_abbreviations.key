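pubcorpus_abbreviations.key — companion key for the abbreviations JSON output.

id                  article identifier
abbreviations       short form -> long form -> list of detection methods:
                    "fulltext_bracket"       found by the bracket-matching
                                             rule in the running text
                    "abbreviations_section"  parsed from a dedicated
                                             abbreviations section
                    The same short form may map to several long forms (e.g.
                    a variant spelling used in the full text); one-sided
                    definitions are never stored.
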