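# Methods

This note documents the models, rules and numerical choices behind
`pubcorpus`, the assumptions they rest on, and what the synthetic fixtures
do and do not demonstrate about real publisher HTML.

## Source configurations

A configuration names element selectors per role (heading, paragraph,
table container, table title/caption/footer). Element names are matched by
regex **full match** (so `h[2-4]` covers three heading levels without
accidentally matching `th`), attribute values by regex **search**, because
publisher class attributes routinely carry suffixes (`section-title-1`,
`section-title-extra`). Unknown keys are rejected rather than ignored: a
typo in a hand-written config should fail loudly, not silently match
nothing. Heading level comes from the `hN` tag when present, otherwise from
the order of the heading selectors in the configuration.

## Full-text model

Headings delineate sections; each paragraph element becomes one passage
whose markup is stripped (entities decoded, tags removed, whitespace runs
collapsed; link anchor text is retained). Parsing is tolerant (`lxml.html`
recovery): unclosed tags in real publisher HTML must never drop text nodes
inside matched containers. A bare `<` not opening a tag is treated as
character data before parsing, which also makes `strip_markup` idempotent.

Passage **offsets count Unicode code points**, starting at 0, over passage
texts only. Code points rather than bytes were chosen for encoding
stability: the same text yields the same offsets regardless of the UTF-8
byte length of any character.

Section titles live in passage infons (`section_title_1..n`), not in the
passage text; the text of a heading element is therefore never duplicated
into passages. Figure captions are passages in reading order flagged
`passage_type: figure_caption`. Passages classified as the abbreviations
section (IAO:0000606) are diverted to the abbreviations output and do not
appear in the BioC file. Superscript and subscript are flattened in full
text (`10<sup>3</sup>` → `103`); tables have their own superscript rule
(below).

## IAO section classification

The packaged lexicon (`data/iao_lexicon.tsv`) pins the IAO *document part*
branch at v2020-06-10 plus curated synonym additions and provisional terms
(ids prefixed `IAO:PROPOSED:`); the header of the file documents the
refresh procedure. Loading validates that every synonym maps to exactly one
term.

* **Normalization** lowercases and removes all non-alphanumerics. Exact
  equality after normalization stands in for LOOM's approximate
  delimiter-insensitive matching because it is deterministic.
* **Fuzzy ratio** is pinned to `2·|LCS|/(|a|+|b|)` on normalized strings
  (SequenceMatcher-style), maximized over each term's label and synonyms,
  threshold 0.8 by default. Pinning a formula (rather than a library) makes
  scores reproducible; a bit-parallel LCS keeps it fast. All entries tied at
  the best score are kept — ambiguous headers may legitimately carry
  several terms.
* **Digraph prediction**: each article's main headers form a directed path
  graph (consecutive duplicates collapsed, so repeats cause no self-edge). A
  synthetic document-start node precedes every chain so leading unmapped
  headers have a left anchor (on PMC pages the "Associated Data" header
  plays this role). Merging a chain increments each traversed node and edge
  weight by one publication; because of the start node, one merge adds
  `|nodes|+1` total node weight and `|edges|+1` total edge weight. For an
  unmapped run between anchors, candidate paths must have interior length
  equal to the run length and interiors consisting of IAO labels; they are
  scored by **summed edge weights** (an interpretive choice — the
  anchor-bounded assignment is well defined, a scoring rule had to be
  fixed), ties keep the union of terms per position. Articles with no
  anchor at all are left unmapped with a warning.
* **Cascade**: lexical, then fuzzy, then digraph; a later stage is never
  consulted once an earlier one succeeds. Sub-headers are classified on
  their own first and inherit the main header's terms only when
  unresolvable.

The digraph serializes to a JSON adjacency list with integer weights;
save/load round-trips exactly.

## Table analysis

Grids are span-expanded before any analysis: a cell spanning rows/columns
is replicated into every covered slot (this is what makes multi-row
spanning headers replicate per covered column), short rows are padded so
the grid is rectangular, and each slot remembers its source cell, so
replication can be told apart from genuine repetition.

* **Headers**: the leading rows whose non-empty cells carry header markup
  (`<th>`/`<thead>`); when no markup marks a header, the first row is taken
  (a structural-cue fallback; a completely headerless grid yields empty
  headers and a warning). Multi-row header strings join top-to-bottom with
  `|`.
* **Sections**: a super row (one source cell spanning the full width), a
  lone first-column string under a headerless first column, or a
  first-column cell spanning several rows closes the current section and
  names the next. Rows before any divider form the unnamed section `""`. A
  first-column cell spanning a *single* row is indistinguishable from a
  data cell under this rule and is treated as data.
* **Column types**: per cell, `numerical` iff it parses as a number,
  `textual` iff it contains no digit, else `mixed`; the column type is the
  modal type over non-super rows, ties break to `mixed`, empty columns are
  `textual` by convention.
* **Sub-tables**: scanning non-super rows top-down, a row in which
  **strictly more than half** of cells mismatch their column's type starts
  a new block whose headers are that row's cells; the k-th split is
  identified `N_k` and copies the parent's metadata. Divider-like rows
  never trigger a split, and column types are re-derived per block.
* **Cell values**: pure numbers (no thousands commas — comma usage is an
  unresolved editorial difference, so such cells stay strings), E-notation,
  and scientific notation `a × 10^b` become JSON numbers; the exponent may
  be superscripted (HTML `<sup>` or Unicode superscript characters) or
  carry an explicit Unicode minus / en-dash / plus sign. Without a
  superscript and without an explicit sign, `5 × 103` is ambiguous and
  stays a string. `true`/`false` stay strings. In text cells all formatting
  is removed **except** superscript, re-encoded as explicit markup
  (`n = 10 <sup>3</sup>`), because flattening would corrupt exponents.
  Empty cells become empty strings to preserve row arity.
* **Identifiers**: header cell `T<table>.C<col>`, data cell
  `T<table>.S<section>.R<row>.C<col>`, all 1-based, rows numbered within
  their section. The table number comes from the title (`Table N`), else
  position.

## Abbreviations

Bracket rule: an innermost parenthesized span with ≥ 2 non-digit characters
is a short-form candidate. The definition is searched within
`min(|short|+5, 2·|short|)` words on each side of the bracket (the
Schwartz–Hearst window convention), left side first. The definition starts
at the rightmost window word whose first character equals the short form's
first character (case-insensitive); the remaining short-form characters
must occur in order in the following text. Characters after the first may
match inside any later position, including after a hyphen in the same word
("genome-wide" donates both *g* and *w* to GWAS) — requiring every
character to open a new word would reject common forms such as
DNA/"deoxyribonucleic acid".

Abbreviation sections are split into entries on semicolons/line breaks and
into pairs on the section's dominant delimiter (colon, equals, comma; ties
break in that order). One-sided entries are dropped. Merging unions method
lists per (short, long) pair and keeps variant long forms as separate
entries; the merge is idempotent and order-insensitive.

## Similarity evaluation

`lcs_similarity(ref, cand) = |LCS|/|ref|` is exact dynamic-programming LCS
(bit-parallel, so units of tens of thousands of characters are cheap); the
windowed heuristics sometimes used for corpus-scale comparisons are not
needed at per-unit granularity. An empty reference scores 1.0 so that
missing optional fields do not poison medians (each such unit is visible in
the report). Differing character spans are extracted from one fixed optimal
alignment; above 20 000 characters per unit the quadratic traceback is
skipped and the record flagged `diff_truncated` — the similarity itself is
always exact. Aggregates are median and interquartile range, appropriate
for the strongly left-skewed distributions these comparisons produce.

## Synthetic fixtures

The generator emits a documented fixture dialect plus a deliberately messy
variant (unclosed inline tags) and optional encoding quirks (Greek letters,
en dashes, micro signs). Section plans cover lexically mappable headers,
typographical variants validated to stay ≥ 0.8 and resolve unambiguously,
and unmappable headers planted between mappable anchors. `gen_corpus`
builds ~70% canonical articles, ~15% typo articles and ~15% plant articles,
so the canonical interior path is strictly heaviest and digraph recovery of
the plants is well defined; its expected digraph weights are tallied
directly from the plans, independent of the digraph code. Table specs are
validated for realizability (span groups must cover all columns; index
sections need ≥ 2 rows; titles must carry the table number they are
identified by).

Default problem sizes — 50 articles and 50 tables in the acceptance run,
20-article corpora in most tests — are large enough to exercise every rule
combination while keeping the whole suite in seconds.

What passing fixtures show: the structural rules, the classification
cascade, offset arithmetic, conservation and round-trip exactness are
implemented as specified. What they do not show: robustness to publisher
quirks absent from the generator (deeply malformed nesting, scripts
injecting content, exotic span layouts), OCR'd table images (out of scope),
or definitions-in-brackets abbreviation patterns, which the bracket rule by
design does not find.

## Known limitations

* Paragraphs under headers mapped to multiple IAO terms keep all terms;
  no text-content-based disambiguation is attempted.
* Header rows without `<th>`/`<thead>` markup fall back to "first row",
  which under-segments tables whose headers are styled purely visually.
* The abbreviation detector finds `long form (SF)` declarations only.
* Linked-table files are associated to articles by the filename stem prefix
  before a `_table` token; other naming conventions need the `--linked-tables`
  glob.
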