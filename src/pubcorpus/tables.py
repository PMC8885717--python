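"""Structural analysis of publication HTML data tables.

The analysis follows a functional/structural decomposition: span-expanded
rectangular grid → navigational header rows (multi-row headers pipe-joined,
spanning headers replicated per covered column) → body segmentation by super
rows and index-column cells → per-column type inference (numerical, textual,
mixed) → sub-table detection where a body row re-declares column headers →
table JSON with per-cell identifiers.

Layout tables are never analyzed: only containers matching the source
configuration's ``table_container`` selectors are processed.
"""

from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import lxml.etree
import lxml.html

from ._schema import load_packaged_schema, validate_json
from .config import SelectorScope, SourceConfig
from .fulltext import ParseWarning, strip_markup

__all__ = [
    "Cell",
    "Grid",
    "RawTable",
    "TableDocument",
    "locate_tables",
    "resolve_headers",
    "segment_sections",
    "classify_columns",
    "split_subtables",
    "parse_cell",
    "process_table",
    "build_table_json",
    "read_table_json",
]

_WS = re.compile(r"\s+")
_TABLE_NUMBER = re.compile(r"[Tt]able\s+(\d+)")

# unicode superscript characters behave exactly like <sup> markup
_SUP_CHARS = "⁰¹²³⁴⁵⁶⁷⁸⁹⁻⁺"
_SUP_MAP = str.maketrans(_SUP_CHARS, "0123456789-+")
_SUP_RUN = re.compile(f"[{_SUP_CHARS}]+")


def _sup_runs_flat(text: str) -> str:
    return text.translate(_SUP_MAP)


def _sup_runs_marked(text: str) -> str:
    return _SUP_RUN.sub(lambda m: f" <sup>{m.group(0).translate(_SUP_MAP)}</sup>", text)

_PLAIN_NUMBER = re.compile(r"[+-]?(?:\d+(?:\.\d+)?|\.\d+)")
_E_NOTATION = re.compile(r"([+-]?(?:\d+(?:\.\d+)?|\.\d+))[eE]([+\-−–]?\d+)")
# scientific notation with an explicit superscripted exponent
_SCI_SUP = re.compile(
    r"([+-]?(?:\d+(?:\.\d+)?|\.\d+))\s*[×x*]\s*10\s*"
    r"<sup>\s*([+\-−–]?\d+)\s*</sup>"
)
# without superscript the exponent sign must be explicit (unicode minus,
# en dash used as minus, hyphen or plus), otherwise "5 × 103" is ambiguous
_SCI_FLAT = re.compile(
    r"([+-]?(?:\d+(?:\.\d+)?|\.\d+))\s*[×x]\s*10\s*([+\-−–]\d+)"
)


@dataclass(frozen=True)
class Cell:
    """One slot of the span-expanded grid.

    ``flat`` has every bit of formatting removed; ``marked`` keeps superscript
    content re-encoded as explicit ``<sup>`` markup so that exponents inside
    text strings keep their meaning. ``origin`` is the (row, col) of the
    source cell that covers this slot, so replicated span content can be told
    apart from genuinely repeated cells.
    """

    flat: str
    marked: str
    is_header: bool
    origin: tuple[int, int]
    rowspan: int = 1
    colspan: int = 1

    @property
    def empty(self) -> bool:
        return self.flat == ""


@dataclass
class Grid:
    """Rectangular matrix of span-expanded cells."""

    cells: list[list[Cell]]

    @property
    def n_rows(self) -> int:
        return len(self.cells)

    @property
    def n_cols(self) -> int:
        return len(self.cells[0]) if self.cells else 0


@dataclass
class RawTable:
    grid: Grid
    number: str
    title: str = ""
    caption: str = ""
    footer: str = ""


@dataclass
class TableDocument:
    """One (sub-)table of the table JSON output."""

    identifier: str
    title: str = ""
    caption: str = ""
    footer: str = ""
    column_headers: list[tuple[str, str]] = field(default_factory=list)
    sections: list[tuple[str, list[list[tuple[str, object]]]]] = field(
        default_factory=list
    )

    @property
    def metadata(self) -> list[tuple[str, str]]:
        out = []
        if self.title:
            out.append(("table title", self.title))
        if self.caption:
            out.append(("table caption", self.caption))
        if self.footer:
            out.append(("table footer", self.footer))
        return out

    def to_dict(self) -> dict:
        return {
            "identifier": self.identifier,
            "metadata": [
                {"section_type": t, "text": text} for t, text in self.metadata
            ],
            "column_headers": [
                {"cell_id": cid, "text": text} for cid, text in self.column_headers
            ],
            "sections": [
                {
                    "section_name": name,
                    "rows": [
                        [{"cell_id": cid, "value": value} for cid, value in row]
                        for row in rows
                    ],
                }
                for name, rows in self.sections
            ],
        }

    @classmethod
    def from_dict(cls, data: dict) -> "TableDocument":
        meta = {m["section_type"]: m["text"] for m in data.get("metadata", [])}
        return cls(
            identifier=data["identifier"],
            title=meta.get("table title", ""),
            caption=meta.get("table caption", ""),
            footer=meta.get("table footer", ""),
            column_headers=[
                (h["cell_id"], h["text"]) for h in data.get("column_headers", [])
            ],
            sections=[
                (
                    s["section_name"],
                    [
                        [(c["cell_id"], c["value"]) for c in row]
                        for row in s["rows"]
                    ],
                )
                for s in data.get("sections", [])
            ],
        )


# ---------------------------------------------------------------------------
# cell text extraction


def _cell_texts(el) -> tuple[str, str]:
    """(flat, marked) renderings of one table cell element."""

    def render(node, keep_sup: bool) -> str:
        parts = [node.text or ""]
        for child in node:
            if not isinstance(child.tag, str):
                parts.append(child.tail or "")
                continue
            if keep_sup and child.tag.lower() == "sup":
                inner = _WS.sub(" ", render(child, keep_sup=False)).strip()
                parts.append(f" <sup>{inner}</sup>")
            else:
                parts.append(render(child, keep_sup))
            parts.append(child.tail or "")
        return "".join(parts)

    flat = _WS.sub(" ", _sup_runs_flat(render(el, keep_sup=False))).strip()
    marked = _WS.sub(" ", _sup_runs_marked(render(el, keep_sup=True))).strip()
    return flat, marked


# ---------------------------------------------------------------------------
# grid construction


def grid_from_table_element(table_el) -> Grid:
    """Span-expand an lxml ``<table>`` element into a rectangular grid.

    Cells spanning rows/columns are replicated into every covered slot; short
    rows are padded with empty cells so the grid is rectangular.
    """
    rows = [
        tr
        for tr in table_el.iter("tr")
        if tr.getparent() is table_el
        or (
            isinstance(tr.getparent().tag, str)
            and tr.getparent().tag.lower() in ("thead", "tbody", "tfoot")
            and tr.getparent().getparent() is table_el
        )
    ]
    occupied: dict[tuple[int, int], Cell] = {}
    n_cols = 0
    for r, tr in enumerate(rows):
        in_head = (
            isinstance(tr.getparent().tag, str)
            and tr.getparent().tag.lower() == "thead"
        )
        c = 0
        for td in tr:
            if not isinstance(td.tag, str) or td.tag.lower() not in ("td", "th"):
                continue
            while (r, c) in occupied:
                c += 1
            try:
                colspan = max(1, int(td.get("colspan", "1")))
            except ValueError:
                colspan = 1
            try:
                rowspan = max(1, int(td.get("rowspan", "1")))
            except ValueError:
                rowspan = 1
            flat, marked = _cell_texts(td)
            cell = Cell(
                flat=flat,
                marked=marked,
                is_header=td.tag.lower() == "th" or in_head,
                origin=(r, c),
                rowspan=rowspan,
                colspan=colspan,
            )
            for dr in range(rowspan):
                for dc in range(colspan):
                    occupied.setdefault((r + dr, c + dc), cell)
            c += colspan
            n_cols = max(n_cols, c)
    n_rows = len(rows)
    if occupied:
        n_rows = max(n_rows, max(r for r, _ in occupied) + 1)
    grid: list[list[Cell]] = []
    for r in range(n_rows):
        row = []
        for c in range(n_cols):
            cell = occupied.get((r, c))
            if cell is None:
                cell = Cell(flat="", marked="", is_header=False, origin=(r, c))
            row.append(cell)
        grid.append(row)
    return Grid(cells=grid)


def locate_tables(
    html_text: str,
    config: SourceConfig,
    mode: str = "inline",
    position_offset: int = 0,
) -> list[RawTable]:
    """Find data-table containers in a document and extract grids + metadata.

    Only nodes matching the configuration's ``table_container`` selectors are
    returned, which excludes layout tables; when no container selector is
    configured, bare ``<table>`` elements are taken. The table number is
    parsed from the title text ("Table N"), else assigned positionally.
    """
    root = lxml.html.document_fromstring(html_text)
    containers = config.by_scope(SelectorScope.TABLE_CONTAINER)

    def match_container(el) -> bool:
        if not isinstance(el.tag, str):
            return False
        tag = el.tag.lower()
        attrs = dict(el.attrib)
        if containers:
            return any(s.matches(tag, attrs) for s in containers)
        return tag == "table"

    found = []
    for el in root.iter():
        if match_container(el) and not any(
            match_container(anc) for anc in el.iterancestors()
        ):
            found.append(el)
    if not found and mode == "linked":
        warnings.warn(
            "linked-table file contains no matching table container",
            ParseWarning,
            stacklevel=2,
        )
        return []

    def meta_text(container, scope: SelectorScope) -> str:
        sels = config.by_scope(scope)
        for el in container.iter():
            if not isinstance(el.tag, str):
                continue
            if any(s.matches(el.tag.lower(), dict(el.attrib)) for s in sels):
                return strip_markup(lxml.etree.tostring(el, encoding="unicode"))
        if scope == SelectorScope.TABLE_CAPTION:
            cap = next(iter(container.iter("caption")), None)
            if cap is not None:
                return strip_markup(lxml.etree.tostring(cap, encoding="unicode"))
        return ""

    out: list[RawTable] = []
    for i, container in enumerate(found):
        table_el = container if container.tag.lower() == "table" else next(
            iter(container.iter("table")), None
        )
        if table_el is None:
            continue
        title = meta_text(container, SelectorScope.TABLE_TITLE)
        caption = meta_text(container, SelectorScope.TABLE_CAPTION)
        footer = meta_text(container, SelectorScope.TABLE_FOOTER)
        m = _TABLE_NUMBER.search(title)
        number = m.group(1) if m else str(position_offset + i + 1)
        out.append(
            RawTable(
                grid=grid_from_table_element(table_el),
                number=number,
                title=title,
                caption=caption,
                footer=footer,
            )
        )
    return out


# ---------------------------------------------------------------------------
# structural analysis


def resolve_headers(grid: Grid) -> tuple[list[str], list[list[Cell]]]:
    """Split the grid into pipe-joined column headers and body rows.

    Header rows are the leading rows whose non-empty cells carry header
    markup (``<th>`` or a ``<thead>`` parent); when the markup gives no
    header at all, the first row is taken (and a warning emitted for a
    completely headerless grid). Strings of a multi-row header are joined
    top-to-bottom with "|"; text replicated by a rowspan appears once per
    covered column, text replicated by a colspan once in each column it
    covers.
    """
    if not grid.cells:
        return [], []
    n_header = 0
    for row in grid.cells:
        if any(c.is_header for c in row if not c.empty) and not any(
            c.is_header is False and not c.empty for c in row
        ):
            n_header += 1
        else:
            break
    if n_header == 0:
        if any(not c.empty for c in grid.cells[0]):
            n_header = 1
        else:
            warnings.warn("headerless grid: all rows treated as body", ParseWarning)
            return [""] * grid.n_cols, list(grid.cells)
    headers = []
    for c in range(grid.n_cols):
        parts = []
        prev_origin = None
        for r in range(n_header):
            cell = grid.cells[r][c]
            if cell.origin == prev_origin:
                continue  # rowspan continuation, text appears once
            prev_origin = cell.origin
            if cell.flat:
                parts.append(cell.flat)
        headers.append("|".join(parts))
    return headers, list(grid.cells[n_header:])


def is_super_row(row: list[Cell], n_cols: int) -> bool:
    """A super row is a single text string spanning the complete row width."""
    if n_cols < 2:
        return False
    origins = {c.origin for c in row}
    return len(origins) == 1 and bool(row[0].flat)


def segment_sections(
    body_rows: list[list[Cell]], headers: list[str]
) -> list[tuple[str, list[list[Cell]]]]:
    """Group body rows into named sections.

    A super row, a headerless-first-column divider row, or a first-column
    cell spanning multiple rows closes the previous section and names the
    next; rows before any divider form the unnamed section "".
    """
    n_cols = len(headers)
    sections: list[tuple[str, list[list[Cell]]]] = []
    name = ""
    rows: list[list[Cell]] = []

    def close() -> None:
        nonlocal rows
        if rows or (sections and sections[-1][0] != name):
            pass
        if rows:
            sections.append((name, rows))
        rows = []

    for r, row in enumerate(body_rows):
        if is_super_row(row, n_cols):
            close()
            name = row[0].flat
            continue
        first = row[0] if row else None
        if (
            first is not None
            and not first.empty
            and headers
            and headers[0] == ""
            and all(c.empty for c in row[1:])
        ):
            # headerless index column: a lone first-column string divides
            close()
            name = first.flat
            continue
        if (
            first is not None
            and not first.empty
            and first.rowspan > 1
            and first.origin[1] == 0
            and _is_span_start(body_rows, r)
        ):
            close()
            name = first.flat
        rows.append(row)
    close()
    if not sections and not body_rows:
        return []
    if not sections:
        sections.append((name, []))
    return sections


def _is_span_start(body_rows: list[list[Cell]], r: int) -> bool:
    """True when row r holds the first body occurrence of its first-column cell."""
    cell = body_rows[r][0]
    return r == 0 or body_rows[r - 1][0].origin != cell.origin


def cell_type(cell: Cell) -> str:
    """numerical | textual | mixed for one cell (numerical iff it parses as a
    number; textual iff it contains no digits; mixed otherwise)."""
    if isinstance(parse_cell(cell), (int, float)):
        return "numerical"
    if not any(ch.isdigit() for ch in cell.flat):
        return "textual"
    return "mixed"


def classify_columns(
    body_rows: list[list[Cell]], super_mask: list[bool] | None = None
) -> list[str]:
    """Column types from the dominant cell type over non-super rows.

    Ties break to "mixed"; a column with no votes (empty table) is "textual"
    by convention.
    """
    if not body_rows:
        return []
    n_cols = len(body_rows[0])
    if super_mask is None:
        super_mask = [is_super_row(row, n_cols) for row in body_rows]
    types: list[str] = []
    for c in range(n_cols):
        counts = {"numerical": 0, "textual": 0, "mixed": 0}
        for row, is_super in zip(body_rows, super_mask):
            if is_super:
                continue
            counts[cell_type(row[c])] += 1
        best = max(counts.values())
        if best == 0:
            types.append("textual")
            continue
        winners = [t for t, n in counts.items() if n == best]
        types.append(winners[0] if len(winners) == 1 else "mixed")
    return types


def split_subtables(
    body_rows: list[list[Cell]],
    column_types: list[str],
    headers: list[str],
) -> list[tuple[list[str], list[list[Cell]]]]:
    """Split the body where a row re-declares column headers.

    Scanning non-super rows top-down, a row in which strictly more than half
    of the cells mismatch their column's inferred type becomes a new header
    row; the rows that follow form a sub-table. Divider-like rows (super rows
    and lone first-column strings) never trigger a split.
    """
    n_cols = len(column_types)
    blocks: list[tuple[list[str], list[list[Cell]]]] = []
    current_headers = list(headers)
    current_rows: list[list[Cell]] = []
    for row in body_rows:
        if is_super_row(row, n_cols) or (
            row and not row[0].empty and all(c.empty for c in row[1:])
        ):
            current_rows.append(row)
            continue
        mismatch = sum(
            1 for c, col_t in zip(row, column_types) if cell_type(c) != col_t
        )
        if mismatch * 2 > n_cols:
            blocks.append((current_headers, current_rows))
            current_headers = [c.flat for c in row]
            current_rows = []
        else:
            current_rows.append(row)
    blocks.append((current_headers, current_rows))
    return blocks


def parse_cell(cell: "Cell | str") -> object:
    """Typed value of a cell: JSON number for purely numeric content
    (scientific notation converted to exponential form), else a string with
    all formatting removed except superscript markup.

    Booleans ("true"/"false") stay strings; a thousands comma makes the cell
    a string; the unicode minus (U+2212), an en dash used as a minus, and
    "×"/"x" are accepted inside scientific notation.
    """
    if isinstance(cell, str):
        marked = _WS.sub(" ", _sup_runs_marked(cell)).strip()
        flat = _WS.sub(
            " ", re.sub(r"</?sup>", "", _sup_runs_flat(cell))
        ).strip()
    else:
        flat, marked = cell.flat, cell.marked
    if flat == "":
        return ""
    m = _PLAIN_NUMBER.fullmatch(flat)
    if m:
        return int(flat) if re.fullmatch(r"[+-]?\d+", flat) else float(flat)
    m = _E_NOTATION.fullmatch(flat)
    if m:
        return float(f"{m.group(1)}e{_exp(m.group(2))}")
    m = _SCI_SUP.fullmatch(marked)
    if m:
        return float(f"{m.group(1)}e{_exp(m.group(2))}")
    m = _SCI_FLAT.fullmatch(flat)
    if m:
        return float(f"{m.group(1)}e{_exp(m.group(2))}")
    return marked if "<sup>" in marked else flat


def _exp(text: str) -> int:
    return int(text.replace("−", "-").replace("–", "-"))


# ---------------------------------------------------------------------------
# assembly


def process_table(raw: RawTable) -> list[TableDocument]:
    """Full structural analysis of one located table: headers, sub-tables,
    sections, typed cells, per-cell identifiers."""
    headers, body = resolve_headers(raw.grid)
    column_types = classify_columns(body)
    blocks = split_subtables(body, column_types, headers)
    docs: list[TableDocument] = []
    for k, (block_headers, rows) in enumerate(blocks):
        if k > 0 and not rows:
            continue  # a trailing header row with no data is dropped
        ident = raw.number if k == 0 else f"{raw.number}_{k}"
        doc = TableDocument(
            identifier=ident,
            title=raw.title,
            caption=raw.caption,
            footer=raw.footer,
        )
        doc.column_headers = [
            (f"T{ident}.C{c + 1}", text) for c, text in enumerate(block_headers)
        ]
        sections = segment_sections(rows, block_headers)
        for s, (name, sec_rows) in enumerate(sections, start=1):
            out_rows = []
            for r, row in enumerate(sec_rows, start=1):
                out_rows.append(
                    [
                        (f"T{ident}.S{s}.R{r}.C{c + 1}", parse_cell(cell))
                        for c, cell in enumerate(row)
                    ]
                )
            doc.sections.append((name, out_rows))
        docs.append(doc)
    return docs


def build_table_json(
    tables: list[TableDocument], path: str | Path, document_id: str = "document"
) -> None:
    """Write the table JSON file for one article (empty table list is valid)."""
    idents = [t.identifier for t in tables]
    if len(set(idents)) != len(idents):
        raise ValueError(f"duplicate table identifiers: {idents}")
    payload = {
        "id": document_id,
        "source": "pubcorpus",
        "key": "pubcorpus_tables.key",
        "tables": [t.to_dict() for t in tables],
    }
    validate_json(payload, load_packaged_schema("tables"))
    Path(path).write_text(
        json.dumps(payload, indent=2, ensure_ascii=False), encoding="utf-8"
    )


def read_table_json(path: str | Path) -> tuple[str, list[TableDocument]]:
    data = json.loads(Path(path).read_text(encoding="utf-8"))
    validate_json(data, load_packaged_schema("tables"))
    return data["id"], [TableDocument.from_dict(t) for t in data["tables"]]
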