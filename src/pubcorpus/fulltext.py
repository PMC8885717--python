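"""Parse full-text publication HTML into an ordered section/passage model and
emit BioC JSON.

Heading elements (as declared by the source configuration) delineate
sections; paragraph elements become passages whose text is stripped of all
markup. Passage offsets count Unicode code points from 0 over passage texts
only. Figure captions are kept inline in reading order. Passages classified
as the abbreviations section (IAO:0000606) are excluded from the BioC output
— they are routed to the abbreviations extractor instead — and table content
is excluded here because tables have their own structured output.
"""

from __future__ import annotations

import html as _htmlmod
import json
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import lxml.etree
import lxml.html

from ._schema import load_packaged_schema, validate_json
from .config import SelectorScope, SourceConfig

__all__ = [
    "Passage",
    "ArticleModel",
    "BioCCollection",
    "ParseWarning",
    "strip_markup",
    "parse_article",
    "build_bioc",
    "write_bioc",
    "read_bioc",
    "ABBREVIATIONS_SECTION_ID",
]

ABBREVIATIONS_SECTION_ID = "IAO:0000606"

_PMC_ID = re.compile(r"PMC\d+")
_WS = re.compile(r"\s+")
# a "<" not opening a tag/comment/close-tag is character data (HTML5 rule);
# escaping it keeps tolerant parsing and strip_markup idempotent
_BARE_LT = re.compile(r"<(?![a-zA-Z/!])")


class ParseWarning(UserWarning):
    """Emitted when a configuration matches nothing in a document."""


def strip_markup(fragment: str) -> str:
    """Remove all tags from a markup fragment, keeping the text.

    Anchor (link) inner text is retained, entity references are decoded and
    whitespace runs collapse to single spaces. Formatting such as super- and
    subscript is flattened ("10<sup>3</sup>" becomes "103"). Idempotent.
    """
    if not fragment or not fragment.strip():
        return ""
    guarded = _BARE_LT.sub("&lt;", fragment)
    try:
        node = lxml.html.fromstring(f"<div>{guarded}</div>")
        text = node.text_content()
    except lxml.etree.ParserError:
        text = _htmlmod.unescape(guarded)
    return _WS.sub(" ", text).strip()


@dataclass
class Passage:
    """One markup-free text unit with the section headings that govern it."""

    text: str
    heading_path: tuple[str, ...] = ()
    offset: int = 0
    iao_terms: list[tuple[str, str]] = field(default_factory=list)
    is_figure_caption: bool = False


@dataclass
class ArticleModel:
    """Ordered passages of one article, figure captions interleaved."""

    document_id: str
    passages: list[Passage] = field(default_factory=list)

    @property
    def figure_captions(self) -> list[Passage]:
        return [p for p in self.passages if p.is_figure_caption]


def document_id_from_filename(name: str | Path) -> str:
    """Filename stem; a PMC id (``PMC\\d+``) in the name is used verbatim."""
    stem = Path(name).stem
    m = _PMC_ID.search(stem)
    return m.group(0) if m else stem


def _heading_level(tag: str, selector_index: int) -> int:
    m = re.fullmatch(r"h([1-6])", tag)
    if m:
        return int(m.group(1))
    return selector_index + 1


def parse_article(
    html_text: str, config: SourceConfig, document_id: str = "document"
) -> ArticleModel:
    """Parse full-text HTML into an ``ArticleModel`` using the source config.

    Parsing is tolerant: malformed fragments are recovered, never fatal.
    Headings maintain a heading-path stack (title, subtitle, ...) and are not
    themselves passages. Content inside table containers is skipped (tables
    are processed separately). If no selector matches at all, a
    ``ParseWarning`` is emitted and the model is empty, signalling a wrong
    configuration for this source.
    """
    model = ArticleModel(document_id=document_id)
    if not html_text or not html_text.strip():
        warnings.warn("empty document", ParseWarning, stacklevel=2)
        return model
    root = lxml.html.document_fromstring(html_text)
    headings = config.by_scope(SelectorScope.HEADING)
    paragraphs = config.by_scope(SelectorScope.PARAGRAPH)
    containers = config.by_scope(SelectorScope.TABLE_CONTAINER)
    meta_scopes = [
        config.by_scope(SelectorScope.TABLE_TITLE),
        config.by_scope(SelectorScope.TABLE_CAPTION),
        config.by_scope(SelectorScope.TABLE_FOOTER),
    ]
    stack: list[tuple[int, str]] = []
    saw_match = False

    def emit(el, caption: bool) -> None:
        text = strip_markup(
            (el.text or "")
            + "".join(
                lxml.etree.tostring(child, encoding="unicode") for child in el
            )
        )
        if text:
            model.passages.append(
                Passage(
                    text=text,
                    heading_path=tuple(title for _, title in stack),
                    is_figure_caption=caption,
                )
            )

    def walk(el) -> None:
        nonlocal saw_match
        if not isinstance(el.tag, str):
            return
        tag = el.tag.lower()
        attrs = dict(el.attrib)
        if tag == "table" or any(s.matches(tag, attrs) for s in containers):
            return  # table content handled by the tables module
        if any(any(s.matches(tag, attrs) for s in scope) for scope in meta_scopes):
            return  # table metadata travels with the table output
        for idx, sel in enumerate(headings):
            if sel.matches(tag, attrs):
                saw_match = True
                level = _heading_level(tag, idx)
                title = strip_markup(lxml.etree.tostring(el, encoding="unicode"))
                while stack and stack[-1][0] >= level:
                    stack.pop()
                if title:
                    stack.append((level, title))
                return
        if tag == "figcaption":
            saw_match = True
            emit(el, caption=True)
            return
        if any(s.matches(tag, attrs) for s in paragraphs):
            saw_match = True
            emit(el, caption=el.getparent() is not None
                 and isinstance(el.getparent().tag, str)
                 and el.getparent().tag.lower() == "figure")
            return
        for child in el:
            walk(child)

    body = root.find("body")
    walk(body if body is not None else root)
    if not saw_match:
        warnings.warn(
            f"no heading or paragraph selector of config "
            f"{config.source_name!r} matched anything in {document_id!r}",
            ParseWarning,
            stacklevel=2,
        )
        model.passages.clear()
    return model


# ---------------------------------------------------------------------------
# BioC


@dataclass
class BioCCollection:
    """A minimal BioC-conformant collection: one document per article, each
    passage carrying section-title and IAO infons plus a code-point offset."""

    source: str = "pubcorpus"
    date: str = ""
    key: str = "pubcorpus_fulltext.key"
    documents: list[dict] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "source": self.source,
            "date": self.date,
            "key": self.key,
            "infons": {},
            "documents": self.documents,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "BioCCollection":
        return cls(
            source=data.get("source", ""),
            date=data.get("date", ""),
            key=data.get("key", ""),
            documents=list(data.get("documents", [])),
        )


def build_bioc(
    model: ArticleModel, classified: list[list[tuple[str, str]]]
) -> BioCCollection:
    """Assemble the BioC collection from a model and its per-passage IAO
    annotations (aligned 1:1 with ``model.passages``).

    Passages annotated as the abbreviations section are excluded (they feed
    the abbreviations output); offsets are recomputed over the passages that
    remain, so they start at 0 and increase by each passage's code-point
    length.
    """
    if len(classified) != len(model.passages):
        raise ValueError(
            f"classification list length {len(classified)} does not match "
            f"passage count {len(model.passages)}"
        )
    passages_out: list[dict] = []
    offset = 0
    for passage, terms in zip(model.passages, classified):
        if any(iao_id == ABBREVIATIONS_SECTION_ID for _, iao_id in terms):
            continue
        infons: dict[str, str] = {}
        for i, title in enumerate(passage.heading_path, start=1):
            infons[f"section_title_{i}"] = title
        for i, (name, iao_id) in enumerate(terms, start=1):
            infons[f"iao_name_{i}"] = name
            infons[f"iao_id_{i}"] = iao_id
        infons["passage_type"] = (
            "figure_caption" if passage.is_figure_caption else "text"
        )
        passages_out.append({"infons": infons, "offset": offset, "text": passage.text})
        offset += len(passage.text)
    return BioCCollection(
        documents=[{"id": model.document_id, "infons": {}, "passages": passages_out}]
    )


def write_bioc(collection: BioCCollection, path: str | Path) -> None:
    """Write UTF-8 BioC JSON validating against the packaged full-text schema."""
    payload = collection.to_dict()
    validate_json(payload, load_packaged_schema("fulltext"))
    Path(path).write_text(
        json.dumps(payload, indent=2, ensure_ascii=False), encoding="utf-8"
    )


def read_bioc(path: str | Path) -> BioCCollection:
    data = json.loads(Path(path).read_text(encoding="utf-8"))
    validate_json(data, load_packaged_schema("fulltext"))
    return BioCCollection.from_dict(data)
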