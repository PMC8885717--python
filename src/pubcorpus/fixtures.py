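"""Publisher-style synthetic articles and tables with exact ground truth.

Every pipeline stage is testable without downloads: the generator emits HTML
in a documented fixture dialect (plus a deliberately messy variant with
unclosed tags to exercise tolerant parsing) together with the BioC, table
and abbreviations JSON the pipeline is expected to produce. The ground truth
is constructed directly from the section/table plans by counting and string
assembly, independent of the parsing code it validates.

The generated material mirrors the structure of open-access biomedical
full texts: IAO-mappable section headers (with typographical variants and
deliberately unmappable headers between mappable anchors), sub-headers,
figure captions in reading order, bracket-declared abbreviations plus a
dedicated abbreviations section, and data tables with multi-row spanning
headers, super rows, index columns and mid-body header re-declarations.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field, replace

from .abbrev import METHOD_FULLTEXT, METHOD_SECTION, AbbreviationSet
from .config import Selector, SelectorScope, SourceConfig, TablesMode
from .sections import (
    START_NODE,
    default_lexicon,
    fuzzy_ratio,
    match_fuzzy,
    match_lexical,
    normalize_header,
)
from .tables import TableDocument

__all__ = [
    "ArticleSpec",
    "SectionPlan",
    "SubPlan",
    "AbbrevPlant",
    "TableSpec",
    "GeneratedArticle",
    "GeneratedTable",
    "CorpusFixture",
    "GenerationError",
    "fixture_config",
    "gen_article",
    "gen_table",
    "gen_corpus",
]


class GenerationError(ValueError):
    """A fixture spec cannot be realized (e.g. a typo falls below the fuzzy
    threshold)."""


def fixture_config() -> SourceConfig:
    """The source configuration describing the fixture dialect."""
    return SourceConfig(
        source_name="fixture-dialect",
        tables_mode=TablesMode.BOTH,
        contributors="generated fixture dialect",
        selectors=(
            Selector(
                element_name="h2",
                attribute_constraints=(("class", r"section-title.*"),),
                scope=SelectorScope.HEADING,
            ),
            Selector(
                element_name="h3",
                attribute_constraints=(("class", r"section-sub"),),
                scope=SelectorScope.HEADING,
            ),
            Selector(
                element_name="p",
                attribute_constraints=(("class", r"paragraph"),),
                scope=SelectorScope.PARAGRAPH,
            ),
            Selector(
                element_name="div",
                attribute_constraints=(("class", r"table-box"),),
                scope=SelectorScope.TABLE_CONTAINER,
            ),
            Selector(
                element_name="p",
                attribute_constraints=(("class", r"table-title"),),
                scope=SelectorScope.TABLE_TITLE,
            ),
            Selector(
                element_name="p",
                attribute_constraints=(("class", r"table-caption"),),
                scope=SelectorScope.TABLE_CAPTION,
            ),
            Selector(
                element_name="p",
                attribute_constraints=(("class", r"table-footer"),),
                scope=SelectorScope.TABLE_FOOTER,
            ),
        ),
    )


# ---------------------------------------------------------------------------
# plans


@dataclass(frozen=True)
class SubPlan:
    """A sub-header inside a section; ``term_id`` when it resolves on its
    own, otherwise it inherits the main header's terms."""

    header: str
    term_id: str | None = None
    n_paragraphs: int = 1


@dataclass(frozen=True)
class SectionPlan:
    header: str
    mode: str  # lexical | typo | unmapped
    term_ids: tuple[str, ...]  # ground-truth IAO ids for this section
    n_paragraphs: int = 1
    subs: tuple[SubPlan, ...] = ()
    with_figure: bool = False


@dataclass(frozen=True)
class AbbrevPlant:
    short: str
    long: str
    placement: str  # fulltext | section | both
    fulltext_variant: str | None = None


@dataclass(frozen=True)
class TableSpec:
    seed: int
    number: int = 1
    col_types: tuple[str, ...] = ("textual", "numerical", "numerical")
    header_depth: int = 1
    span_groups: tuple[tuple[str, int], ...] = ()  # header_depth == 2
    sub_headers: tuple[str, ...] = ("Group", "n", "%")
    section_mode: str = "none"  # none | super | index
    sections: tuple[tuple[str, int], ...] = (("", 3),)
    subtable: tuple[tuple[str, ...], int] | None = None
    title: str = ""  # defaults to "Table <number> Summary"
    caption: str = "A generated table."
    footer: str = "Values are synthetic."
    scientific_cells: bool = False

    def __post_init__(self):
        if self.header_depth == 2 and sum(w for _, w in self.span_groups) != len(
            self.col_types
        ):
            raise GenerationError("span groups must cover every column")
        if len(self.sub_headers) != len(self.col_types):
            raise GenerationError("sub_headers arity must equal column count")
        if self.title and f"Table {self.number}" not in self.title:
            raise GenerationError(
                "the title must carry the table number it is identified by"
            )
        if self.section_mode == "index":
            # a one-row index cell is indistinguishable from a data cell
            if any(name and n_rows < 2 for name, n_rows in self.sections):
                raise GenerationError(
                    "index-column sections need at least two rows"
                )

    @property
    def rendered_title(self) -> str:
        return self.title or f"Table {self.number} Summary"


@dataclass(frozen=True)
class ArticleSpec:
    seed: int
    document_id: str
    sections: tuple[SectionPlan, ...]
    abbreviations: tuple[AbbrevPlant, ...] = ()
    tables: tuple[TableSpec, ...] = ()
    unicode_quirks: bool = False
    messy: bool = False


@dataclass
class GeneratedArticle:
    spec: ArticleSpec
    html: str
    linked_tables: list[tuple[str, str]]  # (filename, html)
    bioc: dict  # ground-truth BioC payload
    abbreviations: AbbreviationSet
    tables: list[TableDocument]
    passage_texts: list[str]  # texts expected in the BioC output, in order


@dataclass
class GeneratedTable:
    spec: TableSpec
    inline_html: str  # container fragment
    linked_html: str  # standalone one-table document
    truth: list[TableDocument]


@dataclass
class CorpusFixture:
    articles: list[GeneratedArticle]
    digraph_nodes: dict[str, int]  # expected node weights (counting oracle)
    digraph_edges: dict[tuple[str, str], int]


# ---------------------------------------------------------------------------
# text synthesis

_WORDS = (
    "the cohort analysis signal model measurement variant protein pathway "
    "estimate robust observed increase effect baseline tissue profile serum "
    "assay control replication marker density plasma"
).split()

_QUIRK_SNIPPETS = (
    "the α-synuclein signal spanned 5–10 µM",
    "β-oxidation differed from the baseline",
)


def _sentence(rng: random.Random, quirks: bool = False) -> str:
    if quirks and rng.random() < 0.35:
        core = rng.choice(_QUIRK_SNIPPETS)
    else:
        core = " ".join(rng.choice(_WORDS) for _ in range(rng.randint(6, 11)))
    return core[0].upper() + core[1:] + "."


def _decorate(plain: str, rng: random.Random) -> str:
    """Embed markup into a sentence without changing its stripped text."""
    words = plain.split(" ")
    style = rng.randint(0, 3)
    if style == 0 and len(words) > 3:
        i = rng.randint(1, len(words) - 2)
        words[i] = f"<i>{words[i]}</i>"
        return " ".join(words)
    if style == 2 and len(words) > 3:
        i = rng.randint(1, len(words) - 2)
        words[i] = f"<b>{words[i]}</b>"
        return " ".join(words)
    return plain


def _link_sentence() -> tuple[str, str]:
    html = 'Context appears in <a href="#f1">Figure 1</a>.'
    return html, "Context appears in Figure 1."


# ---------------------------------------------------------------------------
# article generation


def _term_annotations(term_ids: tuple[str, ...]) -> list[tuple[str, str]]:
    lex = default_lexicon()
    return [(lex.label_of(i), i) for i in term_ids]


def _validate_plan(plan: SectionPlan) -> None:
    lex = default_lexicon()
    if plan.mode == "lexical":
        hit = match_lexical(plan.header, lex)
        if hit is None or (plan.term_ids and hit != plan.term_ids[0]):
            raise GenerationError(
                f"header {plan.header!r} does not lexically resolve to "
                f"{plan.term_ids}"
            )
    elif plan.mode == "typo":
        if match_lexical(plan.header, lex) is not None:
            raise GenerationError(f"typo header {plan.header!r} matches lexically")
        entry = lex.get(plan.term_ids[0])
        best = max(
            fuzzy_ratio(normalize_header(plan.header), normalize_header(name))
            for name in entry.all_names
        )
        if best < 0.8:
            raise GenerationError(
                f"typo header {plan.header!r} falls below the 0.8 threshold "
                f"({best:.3f})"
            )
        ranked = match_fuzzy(plan.header, lex)
        top = ranked[0][1]
        tied = {i for i, s in ranked if s == top}
        if tied != set(plan.term_ids):
            raise GenerationError(
                f"typo header {plan.header!r} resolves ambiguously to {tied}"
            )
    elif plan.mode == "unmapped":
        if match_lexical(plan.header, lex) is not None:
            raise GenerationError(
                f"unmapped header {plan.header!r} is in the lexicon"
            )
        if match_fuzzy(plan.header, lex):
            raise GenerationError(
                f"unmapped header {plan.header!r} fuzzy-matches the lexicon"
            )
    else:
        raise GenerationError(f"unknown section mode {plan.mode!r}")


def gen_article(spec: ArticleSpec) -> GeneratedArticle:
    """Render one article and its exact expected outputs.

    Deterministic: the same spec (same seed) yields byte-identical HTML and
    ground truth on every call.
    """
    rng = random.Random(spec.seed)
    for plan in spec.sections:
        _validate_plan(plan)

    html_parts: list[str] = [
        "<html><head><meta charset=\"utf-8\"><title>",
        spec.document_id,
        "</title></head><body>",
        '<div class="content">',
        f'<h1 class="article-title">Synthetic study {spec.document_id}</h1>',
    ]
    truth_passages: list[dict] = []  # BioC ground truth
    abbrev_truth = AbbreviationSet()

    ft_plants = [p for p in spec.abbreviations if p.placement in ("fulltext", "both")]
    sec_plants = [p for p in spec.abbreviations if p.placement in ("section", "both")]

    def p_tag(html_text: str) -> str:
        if spec.messy and rng.random() < 0.5:
            # unclosed inline span exercises tolerant recovery
            return f'<p class="paragraph"><span class="wrap">{html_text}</p>'
        return f'<p class="paragraph">{html_text}</p>'

    body_sections = [s for s in spec.sections]
    # full-text plants are spread over the body sections deterministically
    plant_slots: dict[tuple[int, int], AbbrevPlant] = {}
    if ft_plants and body_sections:
        for i, plant in enumerate(ft_plants):
            sec_i = i % len(body_sections)
            plant_slots[(sec_i, 0)] = plant

    fig_counter = 0
    for sec_i, plan in enumerate(spec.sections):
        heading_class = "section-title-1" if not spec.messy else "section-title-1 x"
        html_parts.append(f'<h2 class="{heading_class}">{plan.header}</h2>')
        terms = _term_annotations(plan.term_ids)

        def emit_paragraphs(n: int, path: tuple[str, ...], p_terms, slot_sec: int | None):
            nonlocal fig_counter
            for k in range(n):
                plain = _sentence(rng, spec.unicode_quirks)
                html_text = _decorate(plain, rng)
                if rng.random() < 0.25:
                    link_html, link_plain = _link_sentence()
                    html_text += " " + link_html
                    plain += " " + link_plain
                if slot_sec is not None and (slot_sec, k) in plant_slots:
                    plant = plant_slots[(slot_sec, k)]
                    long_ft = plant.fulltext_variant or plant.long
                    extra = f" Analyses used {long_ft} ({plant.short}) throughout."
                    html_text += extra
                    plain += extra
                    abbrev_truth.add(plant.short, long_ft, METHOD_FULLTEXT)
                html_parts.append(p_tag(html_text))
                truth_passages.append(
                    {"text": plain, "path": path, "terms": p_terms, "type": "text"}
                )

        emit_paragraphs(plan.n_paragraphs, (plan.header,), terms, sec_i)
        if plan.with_figure:
            fig_counter += 1
            cap = f"Figure {fig_counter}. " + _sentence(rng)
            html_parts.append(
                f'<figure><figcaption class="fig-cap">{cap}</figcaption></figure>'
            )
            truth_passages.append(
                {
                    "text": cap,
                    "path": (plan.header,),
                    "terms": terms,
                    "type": "figure_caption",
                }
            )
        for sub in plan.subs:
            html_parts.append(f'<h3 class="section-sub">{sub.header}</h3>')
            sub_terms = (
                _term_annotations((sub.term_id,)) if sub.term_id else terms
            )
            emit_paragraphs(sub.n_paragraphs, (plan.header, sub.header), sub_terms, None)

    # dedicated abbreviations section (excluded from BioC by design)
    if sec_plants:
        html_parts.append('<h2 class="section-title-1">Abbreviations</h2>')
        entries = "; ".join(f"{p.short}: {p.long}" for p in sec_plants)
        html_parts.append(p_tag(entries))
        for p in sec_plants:
            abbrev_truth.add(p.short, p.long, METHOD_SECTION)

    # inline tables
    table_truth: list[TableDocument] = []
    linked_files: list[tuple[str, str]] = []
    for t_i, tspec in enumerate(spec.tables):
        gen = gen_table(tspec)
        html_parts.append(gen.inline_html)
        table_truth.extend(gen.truth)
        linked_files.append(
            (f"{spec.document_id}_table_{tspec.number}.html", gen.linked_html)
        )

    html_parts.append("</div></body></html>")

    # assemble ground-truth BioC with code-point offsets over passage texts
    passages_out = []
    offset = 0
    for tp in truth_passages:
        infons: dict[str, str] = {}
        for i, title in enumerate(tp["path"], start=1):
            infons[f"section_title_{i}"] = title
        for i, (name, iao_id) in enumerate(tp["terms"], start=1):
            infons[f"iao_name_{i}"] = name
            infons[f"iao_id_{i}"] = iao_id
        infons["passage_type"] = tp["type"]
        passages_out.append({"infons": infons, "offset": offset, "text": tp["text"]})
        offset += len(tp["text"])
    bioc_truth = {
        "source": "pubcorpus",
        "date": "",
        "key": "pubcorpus_fulltext.key",
        "infons": {},
        "documents": [
            {"id": spec.document_id, "infons": {}, "passages": passages_out}
        ],
    }

    return GeneratedArticle(
        spec=spec,
        html="\n".join(html_parts),
        linked_tables=linked_files,
        bioc=bioc_truth,
        abbreviations=abbrev_truth,
        tables=table_truth,
        passage_texts=[tp["text"] for tp in truth_passages],
    )


# ---------------------------------------------------------------------------
# table generation

_TEXT_POOL = ("low", "high", "medium", "absent", "present", "strong", "weak")


def _cell_for_type(
    rng: random.Random, col_type: str, scientific: bool
) -> tuple[str, object]:
    """(cell HTML, expected typed value)."""
    if col_type == "numerical":
        if scientific:
            mant = rng.randint(1, 9)
            exp = rng.randint(2, 12)
            return (f"{mant} × 10<sup>−{exp}</sup>", float(f"{mant}e-{exp}"))
        value = round(rng.uniform(0.01, 99.99), 2)
        return (repr(value), value)
    if col_type == "textual":
        word = rng.choice(_TEXT_POOL)
        return (word, word)
    word = f"rs{rng.randint(100, 99999)}"
    return (word, word)


def gen_table(spec: TableSpec) -> GeneratedTable:
    """Render one table spec as inline and linked HTML plus ground truth.

    Both renderings contain the identical container fragment, so their
    expected TableDocuments are identical by construction.
    """
    rng = random.Random(spec.seed)
    n_cols = len(spec.col_types)
    ident = str(spec.number)

    # --- headers -----------------------------------------------------------
    head_rows: list[str] = []
    if spec.header_depth == 2:
        tops = "".join(
            f'<th colspan="{w}">{text}</th>' for text, w in spec.span_groups
        )
        head_rows.append(f"<tr>{tops}</tr>")
        truth_headers = []
        for text, w in spec.span_groups:
            for _ in range(w):
                truth_headers.append(text)
        truth_headers = [
            f"{top}|{sub}" for top, sub in zip(truth_headers, spec.sub_headers)
        ]
    else:
        truth_headers = list(spec.sub_headers)
    head_rows.append(
        "<tr>" + "".join(f"<th>{h}</th>" for h in spec.sub_headers) + "</tr>"
    )

    # --- body --------------------------------------------------------------
    body_rows_html: list[str] = []
    truth_sections: list[tuple[str, list[list[object]]]] = []

    def data_row(first_override: str | None = None, skip_first: bool = False):
        cells_html = []
        values: list[object] = []
        for c, col_type in enumerate(spec.col_types):
            if c == 0 and first_override is not None:
                values.append(first_override)
                if not skip_first:
                    cells_html.append(f"<td>{first_override}</td>")
                continue
            sci = (
                spec.scientific_cells
                and col_type == "numerical"
                and rng.random() < 0.4
            )
            html, value = _cell_for_type(rng, col_type, sci)
            cells_html.append(f"<td>{html}</td>")
            values.append(value)
        return cells_html, values

    for name, n_rows in spec.sections:
        rows_truth: list[list[object]] = []
        if spec.section_mode == "super" and name:
            body_rows_html.append(
                f'<tr><td colspan="{n_cols}">{name}</td></tr>'
            )
        for r in range(n_rows):
            if spec.section_mode == "index" and name:
                if r == 0:
                    cells_html, values = data_row(first_override=name)
                    cells_html[0] = (
                        f'<td rowspan="{n_rows}">{name}</td>'
                    )
                else:
                    cells_html, values = data_row(first_override=name, skip_first=True)
            else:
                cells_html, values = data_row()
            body_rows_html.append("<tr>" + "".join(cells_html) + "</tr>")
            rows_truth.append(values)
        truth_sections.append((name, rows_truth))

    docs: list[TableDocument] = []

    def make_doc(
        the_ident: str, headers: list[str], sections: list[tuple[str, list[list[object]]]]
    ) -> TableDocument:
        doc = TableDocument(
            identifier=the_ident,
            title=spec.rendered_title,
            caption=spec.caption,
            footer=spec.footer,
        )
        doc.column_headers = [
            (f"T{the_ident}.C{c + 1}", h) for c, h in enumerate(headers)
        ]
        for s, (name, rows) in enumerate(sections, start=1):
            doc.sections.append(
                (
                    name,
                    [
                        [
                            (f"T{the_ident}.S{s}.R{r + 1}.C{c + 1}", v)
                            for c, v in enumerate(row)
                        ]
                        for r, row in enumerate(rows)
                    ],
                )
            )
        return doc

    docs.append(make_doc(ident, truth_headers, truth_sections))

    if spec.subtable is not None:
        new_headers, n_sub_rows = spec.subtable
        if len(new_headers) != n_cols:
            raise GenerationError("sub-table header arity must equal column count")
        body_rows_html.append(
            "<tr>" + "".join(f"<td>{h}</td>" for h in new_headers) + "</tr>"
        )
        sub_rows: list[list[object]] = []
        for _ in range(n_sub_rows):
            cells_html, values = data_row()
            body_rows_html.append("<tr>" + "".join(cells_html) + "</tr>")
            sub_rows.append(values)
        docs.append(
            make_doc(f"{ident}_1", list(new_headers), [("", sub_rows)])
        )

    table_html = (
        '<div class="table-box">'
        f'<p class="table-title">{spec.rendered_title}</p>'
        f'<p class="table-caption">{spec.caption}</p>'
        "<table><thead>" + "".join(head_rows) + "</thead><tbody>"
        + "".join(body_rows_html)
        + "</tbody></table>"
        f'<p class="table-footer">{spec.footer}</p>'
        "</div>"
    )
    linked_html = f"<html><body>{table_html}</body></html>"
    return GeneratedTable(
        spec=spec, inline_html=table_html, linked_html=linked_html, truth=docs
    )


# ---------------------------------------------------------------------------
# corpus generation

_CANONICAL_IDS = {
    "Abstract": ("IAO:0000315",),
    "Introduction": ("IAO:0000316",),
    "Methods": ("IAO:0000317",),
    "Materials and Methods": ("IAO:0000317",),
    "Results": ("IAO:0000318",),
    "Discussion": ("IAO:0000319",),
    "Conclusion": ("IAO:0000615",),
    "Acknowledgements": ("IAO:0000324",),
    "References": ("IAO:0000320",),
}

_TYPO_HEADERS = (
    ("Experemintal Section", "IAO:0000317"),
    ("Statisical Analysis", "IAO:0000644"),
    ("Backgroud", "IAO:0000316"),
)

_UNMAPPED_METHODS = ("Cohort Assembly", "Assay Logistics", "Recruitment Machinery")
_UNMAPPED_DISCUSSION = ("Post Hoc Musings", "Broader Reverberations")


def _plan(header: str, n_paragraphs: int = 1, **kw) -> SectionPlan:
    return SectionPlan(
        header=header,
        mode="lexical",
        term_ids=_CANONICAL_IDS[header],
        n_paragraphs=n_paragraphs,
        **kw,
    )


def gen_corpus(n: int, seed: int = 0) -> CorpusFixture:
    """A miniature corpus plus the exact digraph implied by its section plans.

    Roughly 70% of articles follow the canonical chain (abstract,
    introduction, methods, results, discussion, ...), ~15% carry a
    typographical header variant, and ~15% replace a canonical header with
    an unmappable one between two mappable anchors; the canonical interior
    is always strictly heavier than any alternative, so digraph prediction
    of the plants is well-defined. Node/edge weights are tallied directly
    from the plans (counting oracle), independent of the digraph code.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = random.Random(seed)
    articles: list[GeneratedArticle] = []
    node_w: dict[str, int] = {}
    edge_w: dict[tuple[str, str], int] = {}
    lex = default_lexicon()

    for i in range(n):
        roll = rng.random() if n > 3 else 1.0  # tiny corpora stay canonical
        methods_header = rng.choice(["Methods", "Materials and Methods"])
        plans = [
            _plan("Abstract"),
            _plan("Introduction", n_paragraphs=rng.randint(1, 2)),
            _plan(methods_header, n_paragraphs=rng.randint(1, 2)),
            _plan("Results", n_paragraphs=rng.randint(1, 2), with_figure=rng.random() < 0.4),
            _plan("Discussion"),
            _plan("Conclusion"),
        ]
        if rng.random() < 0.5:
            plans.append(_plan("Acknowledgements"))
        if rng.random() < 0.5:
            plans.append(_plan("References"))

        if roll < 0.15:
            # typo article: methods-slot header becomes a typographical variant
            header, term = _TYPO_HEADERS[i % len(_TYPO_HEADERS)]
            slot = 2 if term in ("IAO:0000317", "IAO:0000644") else 1
            plans[slot] = SectionPlan(
                header=header, mode="typo", term_ids=(term,),
                n_paragraphs=plans[slot].n_paragraphs,
            )
        elif roll < 0.30:
            # unmapped plant between two lexical anchors
            if rng.random() < 0.5:
                header = _UNMAPPED_METHODS[i % len(_UNMAPPED_METHODS)]
                plans[2] = SectionPlan(
                    header=header, mode="unmapped", term_ids=("IAO:0000317",),
                    n_paragraphs=plans[2].n_paragraphs,
                )
            else:
                header = _UNMAPPED_DISCUSSION[i % len(_UNMAPPED_DISCUSSION)]
                plans[4] = SectionPlan(
                    header=header, mode="unmapped", term_ids=("IAO:0000319",),
                )

        spec = ArticleSpec(
            seed=rng.randrange(2**31),
            document_id=f"SYN{i + 1:04d}",
            sections=tuple(plans),
        )
        articles.append(gen_article(spec))

        # counting oracle for the digraph: mapped headers under their IAO
        # label (typos resolve by fuzzy matching), unmapped under their
        # normalized text; a document-start node precedes every chain
        labels = [START_NODE]
        for plan in plans:
            if plan.mode == "unmapped":
                labels.append(normalize_header(plan.header))
            else:
                labels.append(lex.label_of(plan.term_ids[0]))
        for label in labels:
            node_w[label] = node_w.get(label, 0) + 1
        for u, v in zip(labels, labels[1:]):
            edge_w[(u, v)] = edge_w.get((u, v), 0) + 1

    return CorpusFixture(articles=articles, digraph_nodes=node_w, digraph_edges=edge_w)
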