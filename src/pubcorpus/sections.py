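"""Classify publication section headers to IAO *document part* terms.

Three cascading strategies are applied per header:

1. **Lexical (LOOM-style)** — case- and punctuation-insensitive equality
   between the header and a term's preferred label or any synonym.
2. **Fuzzy** — LCS-based similarity ``2*LCS/(|a|+|b|)`` on the normalized
   strings, at a configurable threshold (default 0.8), so typographical
   variants such as "experemintal section" still resolve to the methods
   section.
3. **Digraph prediction** — headers that neither strategy resolves are
   assigned from a weighted digraph of section-header order accumulated over
   many publications, anchored on the nearest mapped headers before and after
   the unresolved run.

Each article contributes a directed path graph (DPG): the linear chain of its
main headers in reading order with consecutive duplicates collapsed, so the
chain has no cycles and no self-edges. Merging one DPG into the corpus
digraph increments every traversed node and edge weight by one publication.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import networkx as nx

from ._lcs import lcs_length

try:  # package data; falls back to the source tree for in-place use
    from importlib.resources import files as _pkg_files
except ImportError:  # pragma: no cover
    _pkg_files = None

__all__ = [
    "IAOLexicon",
    "FuzzyConfig",
    "DPG",
    "DPGNode",
    "SectionDigraph",
    "START_NODE",
    "load_lexicon",
    "default_lexicon",
    "normalize_header",
    "match_lexical",
    "match_fuzzy",
    "build_dpg",
    "accumulate_digraph",
    "predict_unmapped",
    "classify_sections",
    "SectionWarning",
]

#: synthetic node preceding every DPG so that leading unresolved headers have
#: a left anchor (plays the role PMC's "Associated Data" header plays on PMC
#: pages, which reliably precedes the abstract)
START_NODE = "__document_start__"

_NON_ALNUM = re.compile(r"[^a-z0-9]+")


class SectionWarning(UserWarning):
    """Emitted when a header or passage cannot be assigned any IAO term."""


def normalize_header(text: str) -> str:
    """LOOM-style normalization: lowercase, all non-alphanumerics removed.

    Idempotent: ``normalize_header(normalize_header(x)) == normalize_header(x)``.
    """
    return _NON_ALNUM.sub("", text.lower())


@dataclass(frozen=True)
class LexiconEntry:
    iao_id: str
    label: str
    synonyms: tuple[str, ...]

    @property
    def all_names(self) -> tuple[str, ...]:
        return (self.label,) + self.synonyms


class IAOLexicon:
    """IAO document-part terms with preferred labels and synonyms.

    Every synonym (after normalization) maps to exactly one entry; this is
    validated at load time.
    """

    def __init__(self, entries: list[LexiconEntry], version: str = "unversioned"):
        self.entries = list(entries)
        self.version = version
        self._by_id: dict[str, LexiconEntry] = {}
        self._by_norm: dict[str, LexiconEntry] = {}
        for entry in self.entries:
            if entry.iao_id in self._by_id:
                raise ValueError(f"duplicate term id {entry.iao_id}")
            self._by_id[entry.iao_id] = entry
            for name in entry.all_names:
                key = normalize_header(name)
                owner = self._by_norm.setdefault(key, entry)
                if owner.iao_id != entry.iao_id:
                    raise ValueError(
                        f"synonym {name!r} maps to both {owner.iao_id} and {entry.iao_id}"
                    )

    def __len__(self) -> int:
        return len(self.entries)

    def get(self, iao_id: str) -> LexiconEntry | None:
        return self._by_id.get(iao_id)

    def lookup_normalized(self, key: str) -> LexiconEntry | None:
        return self._by_norm.get(key)

    def label_of(self, iao_id: str) -> str:
        return self._by_id[iao_id].label

    def id_of_label(self, label: str) -> str | None:
        entry = self._by_norm.get(normalize_header(label))
        if entry is not None and normalize_header(entry.label) == normalize_header(label):
            return entry.iao_id
        return None


def load_lexicon(path: str | Path, version: str | None = None) -> IAOLexicon:
    """Read a lexicon TSV (``iao_id<TAB>label<TAB>syn1|syn2|...``; '#' comments)."""
    path = Path(path)
    entries = []
    for line in path.read_text(encoding="utf-8").splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise ValueError(f"malformed lexicon line: {line!r}")
        iao_id, label, syn_field = parts
        synonyms = tuple(dict.fromkeys(s.strip() for s in syn_field.split("|") if s.strip()))
        entries.append(LexiconEntry(iao_id=iao_id, label=label, synonyms=synonyms))
    return IAOLexicon(entries, version=version or path.stem)


_DEFAULT_LEXICON: IAOLexicon | None = None


def default_lexicon() -> IAOLexicon:
    """The packaged lexicon (IAO v2020-06-10 document parts + curated additions)."""
    global _DEFAULT_LEXICON
    if _DEFAULT_LEXICON is None:
        data = _pkg_files("pubcorpus").joinpath("data/iao_lexicon.tsv")
        _DEFAULT_LEXICON = load_lexicon(Path(str(data)), version="iao-2020-06-10+curated")
    return _DEFAULT_LEXICON


@dataclass(frozen=True)
class FuzzyConfig:
    """Similarity threshold for the fuzzy header matcher (ratio in (0, 1])."""

    threshold: float = 0.8

    def __post_init__(self):
        if not (0 < self.threshold <= 1):
            raise ValueError("threshold must be in (0, 1]")


def match_lexical(header: str, lexicon: IAOLexicon) -> str | None:
    """Exact match of the normalized header against labels and synonyms."""
    entry = lexicon.lookup_normalized(normalize_header(header))
    return entry.iao_id if entry is not None else None


def fuzzy_ratio(a: str, b: str) -> float:
    """``2*LCS(a, b) / (|a| + |b|)``; 1.0 when both strings are empty."""
    denom = len(a) + len(b)
    if denom == 0:
        return 1.0
    return 2.0 * lcs_length(a, b) / denom


def match_fuzzy(
    header: str, lexicon: IAOLexicon, cfg: FuzzyConfig = FuzzyConfig()
) -> list[tuple[str, float]]:
    """All entries whose best label/synonym similarity reaches the threshold.

    The score per entry is the maximum ratio over its preferred label and
    synonyms, computed on normalized strings. Sorted by descending score, ties
    by term id for determinism.
    """
    norm = normalize_header(header)
    scored: list[tuple[str, float]] = []
    for entry in lexicon.entries:
        best = 0.0
        for name in entry.all_names:
            r = fuzzy_ratio(norm, normalize_header(name))
            if r > best:
                best = r
        if best >= cfg.threshold:
            scored.append((entry.iao_id, best))
    scored.sort(key=lambda t: (-t[1], t[0]))
    return scored


def resolve_header(
    header: str, lexicon: IAOLexicon, cfg: FuzzyConfig = FuzzyConfig()
) -> tuple[tuple[str, ...], str]:
    """Cascade lexical → fuzzy for one header.

    Returns ``(term ids, status)`` with status in {"lexical", "fuzzy",
    "unmapped"}. Fuzzy keeps every entry tied at the best score (ambiguous
    headers may legitimately carry several terms); if the lexical step
    succeeds the fuzzy matcher is never consulted.
    """
    hit = match_lexical(header, lexicon)
    if hit is not None:
        return (hit,), "lexical"
    fuzzy = match_fuzzy(header, lexicon, cfg)
    if fuzzy:
        top = fuzzy[0][1]
        return tuple(i for i, s in fuzzy if s == top), "fuzzy"
    return (), "unmapped"


# ---------------------------------------------------------------------------
# directed path graphs and the corpus digraph


@dataclass(frozen=True)
class DPGNode:
    header: str
    normalized: str
    term_ids: tuple[str, ...]  # empty = unmapped
    status: str  # lexical | fuzzy | predicted | unmapped

    @property
    def mapped(self) -> bool:
        return bool(self.term_ids)


@dataclass
class DPG:
    """One article's linear chain of main headers, duplicates collapsed."""

    nodes: list[DPGNode] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.nodes)

    @property
    def edges(self) -> list[tuple[DPGNode, DPGNode]]:
        return list(zip(self.nodes, self.nodes[1:]))


def build_dpg(
    headers: list[str],
    lexicon: IAOLexicon,
    cfg: FuzzyConfig = FuzzyConfig(),
) -> DPG:
    """Build the DPG for an ordered list of main headers.

    Consecutive headers with identical normalization collapse into one node
    (so repeats never create self-edges); each node is tagged with its
    lexical/fuzzy mapping outcome or left unmapped.
    """
    nodes: list[DPGNode] = []
    for header in headers:
        norm = normalize_header(header)
        if nodes and nodes[-1].normalized == norm:
            continue
        term_ids, status = resolve_header(header, lexicon, cfg)
        nodes.append(DPGNode(header=header, normalized=norm, term_ids=term_ids, status=status))
    return DPG(nodes=nodes)


def _node_key(node: DPGNode, lexicon: IAOLexicon) -> str:
    """Digraph label for a DPG node: the primary term's preferred label when
    mapped, otherwise the normalized header text."""
    if node.mapped:
        return lexicon.label_of(node.term_ids[0])
    return node.normalized


class SectionDigraph:
    """Weighted digraph of section-header order across publications.

    Node and edge weights count the number of publications exhibiting each
    header / transition. A synthetic document-start node precedes every merged
    chain.
    """

    def __init__(self) -> None:
        self.graph = nx.DiGraph()

    # -- weights ------------------------------------------------------------
    def node_weight(self, label: str) -> int:
        return self.graph.nodes[label]["weight"] if label in self.graph else 0

    def edge_weight(self, u: str, v: str) -> int:
        return self.graph.edges[u, v]["weight"] if self.graph.has_edge(u, v) else 0

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def _bump_node(self, label: str) -> None:
        if label in self.graph:
            self.graph.nodes[label]["weight"] += 1
        else:
            self.graph.add_node(label, weight=1)

    def _bump_edge(self, u: str, v: str) -> None:
        if self.graph.has_edge(u, v):
            self.graph.edges[u, v]["weight"] += 1
        else:
            self.graph.add_edge(u, v, weight=1)

    # -- persistence --------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "nodes": {n: d["weight"] for n, d in sorted(self.graph.nodes(data=True))},
            "edges": [
                {"from": u, "to": v, "weight": d["weight"]}
                for u, v, d in sorted(self.graph.edges(data=True))
            ],
        }

    @classmethod
    def from_dict(cls, data: dict) -> "SectionDigraph":
        dg = cls()
        for label, w in data.get("nodes", {}).items():
            dg.graph.add_node(label, weight=int(w))
        for edge in data.get("edges", []):
            dg.graph.add_edge(edge["from"], edge["to"], weight=int(edge["weight"]))
        return dg

    def save(self, path: str | Path) -> None:
        import json

        Path(path).write_text(
            json.dumps(self.to_dict(), indent=1, ensure_ascii=False), encoding="utf-8"
        )

    @classmethod
    def load(cls, path: str | Path) -> "SectionDigraph":
        import json

        return cls.from_dict(json.loads(Path(path).read_text(encoding="utf-8")))


def accumulate_digraph(digraph: SectionDigraph, dpg: DPG, lexicon: IAOLexicon) -> SectionDigraph:
    """Merge one article's DPG into the corpus digraph (in place; returned).

    Every traversed node and edge weight is incremented by exactly 1; mapped
    nodes are stored under their IAO preferred label, unmapped nodes under the
    normalized header text. An empty DPG leaves the digraph unchanged.
    """
    if not dpg.nodes:
        return digraph
    keys = [START_NODE] + [_node_key(n, lexicon) for n in dpg.nodes]
    for key in keys:
        digraph._bump_node(key)
    for u, v in zip(keys, keys[1:]):
        digraph._bump_edge(u, v)
    return digraph


def _paths_between(
    digraph: SectionDigraph, a: str, b: str | None, interior: int
) -> list[tuple[list[str], int]]:
    """Simple directed paths from ``a`` (to ``b`` when given) with exactly
    ``interior`` interior nodes, scored by the sum of traversed edge weights."""
    g = digraph.graph
    if a not in g:
        return []
    results: list[tuple[list[str], int]] = []

    def dfs(path: list[str], score: int) -> None:
        depth = len(path) - 1
        last = path[-1]
        if b is not None:
            if depth == interior:
                if g.has_edge(last, b):
                    results.append((path[1:], score + g.edges[last, b]["weight"]))
                return
        elif depth == interior:
            results.append((path[1:], score))
            return
        for nxt in g.successors(last):
            if nxt in path or nxt == b or nxt == START_NODE:
                continue
            dfs(path + [nxt], score + g.edges[last, nxt]["weight"])

    dfs([a], 0)
    return results


def predict_unmapped(
    dpg: DPG, digraph: SectionDigraph, lexicon: IAOLexicon
) -> DPG:
    """Assign IAO terms to unmapped DPG nodes from the corpus digraph.

    For each maximal run of consecutive unmapped nodes, the nearest preceding
    mapped node (or the document-start node) anchors the left end and the
    nearest following mapped node (if any) the right end. Candidate
    assignments are the interior nodes of simple digraph paths between the
    anchors whose interior length equals the run length, restricted to
    interior nodes that are IAO preferred labels; paths are scored by their
    summed edge weights and ties retain the union of terms per position.

    A DPG with no mapped node at all is returned unchanged with a warning.
    """
    if all(n.mapped for n in dpg.nodes):
        return dpg
    if not any(n.mapped for n in dpg.nodes):
        warnings.warn(
            "no anchor headers: digraph prediction skipped for this article",
            SectionWarning,
            stacklevel=2,
        )
        return dpg

    nodes = list(dpg.nodes)
    out: list[DPGNode] = list(nodes)
    i = 0
    while i < len(nodes):
        if nodes[i].mapped:
            i += 1
            continue
        j = i
        while j < len(nodes) and not nodes[j].mapped:
            j += 1
        run = list(range(i, j))  # unmapped run [i, j)
        left = _node_key(nodes[i - 1], lexicon) if i > 0 else START_NODE
        right = _node_key(nodes[j], lexicon) if j < len(nodes) else None
        candidates = _paths_between(digraph, left, right, len(run))
        # only paths whose interior consists of IAO preferred labels can
        # donate terms
        term_paths = []
        for interior, score in candidates:
            ids = [lexicon.id_of_label(lbl) for lbl in interior]
            if all(x is not None for x in ids):
                term_paths.append((ids, score))
        if term_paths:
            best = max(score for _, score in term_paths)
            winners = [ids for ids, score in term_paths if score == best]
            for pos, idx in enumerate(run):
                merged = tuple(dict.fromkeys(ids[pos] for ids in winners))
                out[idx] = replace(nodes[idx], term_ids=merged, status="predicted")
        i = j
    return DPG(nodes=out)


# ---------------------------------------------------------------------------
# article-level classification


def classify_sections(
    model,
    lexicon: IAOLexicon | None = None,
    digraph: SectionDigraph | None = None,
    cfg: FuzzyConfig = FuzzyConfig(),
) -> list[list[tuple[str, str]]]:
    """Per-passage IAO annotations for an ``ArticleModel``, cascade order
    lexical → fuzzy → digraph.

    Main headers (the first element of each passage's heading path) form the
    article's DPG; unresolved main headers are predicted from the corpus
    digraph when one is supplied. A sub-header is classified on its own first
    and only inherits its main header's terms when unresolvable. Passages
    whose headers resolve nowhere get an empty annotation list and a warning.

    Returns one ``[(iao_name, iao_id), ...]`` list per passage, aligned with
    ``model.passages``.
    """
    lexicon = lexicon or default_lexicon()
    mains: list[str] = []
    for passage in model.passages:
        if passage.heading_path:
            main = passage.heading_path[0]
            if not mains or normalize_header(mains[-1]) != normalize_header(main):
                mains.append(main)
    dpg = build_dpg(mains, lexicon, cfg)
    if digraph is not None and digraph.n_nodes and any(n.mapped for n in dpg.nodes):
        dpg = predict_unmapped(dpg, digraph, lexicon)
    by_norm = {node.normalized: node for node in dpg.nodes}

    def terms_of_ids(ids: tuple[str, ...]) -> list[tuple[str, str]]:
        return [(lexicon.label_of(i), i) for i in ids]

    annotations: list[list[tuple[str, str]]] = []
    for passage in model.passages:
        terms: list[tuple[str, str]] = []
        if passage.heading_path:
            deepest = passage.heading_path[-1]
            if len(passage.heading_path) > 1:
                ids, status = resolve_header(deepest, lexicon, cfg)
                if status != "unmapped":
                    terms = terms_of_ids(ids)
            if not terms:
                node = by_norm.get(normalize_header(passage.heading_path[0]))
                if node is not None and node.mapped:
                    terms = terms_of_ids(node.term_ids)
        if not terms:
            warnings.warn(
                f"passage under heading {passage.heading_path!r} could not be "
                "assigned any IAO term",
                SectionWarning,
                stacklevel=2,
            )
        annotations.append(terms)
    return annotations
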