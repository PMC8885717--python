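# IAO document-part lexicon, v2020-06-10 plus curated synonym additions and
# proposed terms. Proposed terms without an official identifier carry the
# provisional prefix IAO:PROPOSED:. Columns: iao_id, preferred_label,
# pipe-separated synonyms. Matching is on the LOOM-style normalization of the
# label and every synonym. To refresh, regenerate from the IAO document-part
# branch and re-append the curated rows.
IAO:0000606	abbreviations section	abbreviations|abbreviations list|abbreviations used|list of abbreviations|list of abbreviations used|abbreviation and acronyms|abbreviation list|abbreviations and acronyms|abbreviations used in this paper|definitions for abbreviations|glossary|key abbreviations|non-standard abbreviations|nonstandard abbreviations|nonstandard abbreviations and acronyms
IAO:0000315	abstract	abstract|precis
IAO:0000324	acknowledgements section	acknowledgments|acknowledgements|acknowledgment|acknowledgement|acknowledgments and disclaimer
IAO:0000323	author contributions section	author contributions|contributions by the authors|authors' contribution|authors' contributions|authors' roles|contributorship|main authors by consortium and author contributions
IAO:0000607	author information section	author information|authors' information|biographies|contributor information
IAO:0000611	availability section	availability|availability and requirements|availability of data|availability of data and materials|data archiving|data availability|data availability statement|data sharing statement
IAO:0000615	conclusion section	concluding remarks|conclusion|conclusions|findings|summary|conclusion and perspectives|summary and conclusion
IAO:0000616	conflict of interest section	competing interests|conflict of interest|conflict of interest statement|declaration of competing interests|disclosure of potential conflicts of interest|authors' disclosures of potential conflicts of interest|competing financial interests|conflict of interests|conflicts of interest|declaration of competing interest|declaration of interest|declaration of interests|disclosure of conflict of interest|duality of interest|statement of interest
IAO:0000618	consent section	consent|informed consent
IAO:0000319	discussion section	discussion|discussion section|discussions
IAO:0000620	ethical approval section	ethical approval|ethics approval and consent to participate|ethical requirements|ethics|ethics statement
IAO:0000325	footnote section	endnote|footnote|footnotes
IAO:0000623	funding source declaration section	funding|funding information|funding sources|funding statement|funding/support|source of funding|sources of funding|financial support|grants|role of the funding source|study funding
IAO:0000625	future directions section	future challenges|future considerations|future developments|future directions|future outlook|future perspectives|future plans|future prospects|future research|future research directions|future studies|future work|outlook
IAO:0000316	introduction section	background|introduction|introductory paragraph
IAO:0000633	materials section	materials|data|data description
IAO:0000317	methods section	experimental|experimental procedures|experimental section|materials and methods|methods|analytical methods|concise methods|experimental methods|method|methodology|method validation|methods and design|methods and procedures|methods and tools|methods/design|online methods|star methods|study design|study design and methods
IAO:0000320	references section	bibliography|literature cited|references|reference|reference list|selected references|web site references
IAO:0000644	statistical analysis section	statistical analysis|statistical methods|statistical methods and analysis|statistics
IAO:0000631	study limitations section	limitations|study limitations|strengths and limitations|study strengths and limitations
IAO:0000326	supplementary material section	additional information|appendix|supplemental information|supplementary material|supporting information|additional file|additional files|additional information and declarations|additional points|electronic supplementary material|electronic supplementary materials|online content|supplemental data|supplemental material|supplementary data|supplementary figures and tables|supplementary files|supplementary information|supplementary materials|supplementary materials figures|supplementary materials figures and tables|supplementary materials table|supplementary materials tables
IAO:0000318	results section	results|result
IAO:0000635	patients section	patients
IAO:PROPOSED:disclosure	disclosure section	author disclosure statement|declarations|disclosure|disclosure statement|disclosures
IAO:PROPOSED:graphical_abstract	graphical abstract	central illustration|graphical abstract|toc image|visual abstract
IAO:PROPOSED:highlights	highlights section	author summary|editors' summary|highlights|key points|overview|research in context|significance|toc
IAO:PROPOSED:participants	participants section	participants|sample
IAO:PROPOSED:table_title	table title	table title
IAO:PROPOSED:table_caption	table caption	table caption
IAO:PROPOSED:table_footer	table footer	table footer|table key|table note|table notes
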