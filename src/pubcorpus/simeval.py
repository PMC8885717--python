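"""Longest-common-subsequence similarity between two pipeline outputs.

The unidirectional similarity of a reference string inside a candidate is
``|LCS(reference, candidate)| / |reference|`` — the proportion of reference
characters that appear in the candidate in the same order. It is
deliberately non-symmetric: a candidate may legitimately carry more content
(figure links, references) without being penalized. The bidirectional
variant takes the maximum over both directions, which matches a
Levenshtein-style similarity for transforming the larger string into the
smaller one while still exposing the differing characters.

Comparisons run per unit (paragraph or table cell) and aggregate the unit
similarities as median and interquartile range, the robust summaries
appropriate for strongly left-skewed similarity distributions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from statistics import median

import numpy as np

from ._lcs import lcs_length, lcs_matched_mask

__all__ = [
    "UnitRecord",
    "SimilarityReport",
    "lcs_similarity",
    "bidirectional_similarity",
    "diff_spans",
    "compare_outputs",
    "PairingError",
]

#: above this reference length the quadratic traceback for difference spans
#: is skipped (the similarity itself is still exact)
DIFF_SPAN_LIMIT = 20_000


class PairingError(ValueError):
    """Two collections are structurally incomparable."""


def lcs_similarity(reference: str, candidate: str) -> float:
    """``|LCS| / |reference|``; an empty reference scores 1.0 by convention
    (a missing optional field should not poison aggregate medians)."""
    if not reference:
        return 1.0
    return lcs_length(reference, candidate) / len(reference)


def bidirectional_similarity(a: str, b: str) -> float:
    """Maximum of the two unidirectional similarities; symmetric."""
    return max(lcs_similarity(a, b), lcs_similarity(b, a))


def diff_spans(reference: str, candidate: str) -> list[tuple[int, int, str]]:
    """Maximal runs of reference characters outside one optimal LCS
    alignment, as ``(start, end, text)`` with end exclusive.

    Empty exactly when every reference character is retained (similarity 1).
    """
    mask = lcs_matched_mask(reference, candidate)
    spans: list[tuple[int, int, str]] = []
    i = 0
    n = len(reference)
    while i < n:
        if mask[i]:
            i += 1
            continue
        j = i
        while j < n and not mask[j]:
            j += 1
        spans.append((i, j, reference[i:j]))
        i = j
    return spans


@dataclass
class UnitRecord:
    reference_id: str
    candidate_id: str
    similarity: float
    diffs: list[tuple[int, int, str]] = field(default_factory=list)
    diff_truncated: bool = False

    def to_dict(self) -> dict:
        return {
            "reference_id": self.reference_id,
            "candidate_id": self.candidate_id,
            "similarity": self.similarity,
            "diffs": [
                {"start": s, "end": e, "text": t} for s, e, t in self.diffs
            ],
            "diff_truncated": self.diff_truncated,
        }


@dataclass
class SimilarityReport:
    granularity: str
    records: list[UnitRecord] = field(default_factory=list)

    @property
    def similarities(self) -> list[float]:
        return [r.similarity for r in self.records]

    @property
    def median(self) -> float:
        return float(median(self.similarities)) if self.records else 1.0

    @property
    def iqr(self) -> tuple[float, float]:
        if not self.records:
            return (1.0, 1.0)
        q1, q3 = np.percentile(self.similarities, [25, 75])
        return (float(q1), float(q3))

    def to_dict(self) -> dict:
        q1, q3 = self.iqr
        return {
            "granularity": self.granularity,
            "n_units": len(self.records),
            "median": self.median,
            "iqr": [q1, q3],
            "records": [r.to_dict() for r in self.records],
        }

    def write_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(self.to_dict(), indent=2, ensure_ascii=False),
            encoding="utf-8",
        )

    def write_diff_text(self, path: str | Path) -> None:
        """Human-readable side-by-side listing of the units that differ."""
        lines = []
        for r in self.records:
            if r.similarity == 1.0 and not r.diffs:
                continue
            lines.append(f"== {r.reference_id} vs {r.candidate_id} "
                         f"(similarity {r.similarity:.4f})")
            for s, e, t in r.diffs:
                lines.append(f"   ref[{s}:{e}] only: {t!r}")
            if r.diff_truncated:
                lines.append("   (diff extraction skipped: unit too long)")
        if not lines:
            lines = ["(no differences)"]
        Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def _unit_record(ref_id: str, cand_id: str, ref: str, cand: str) -> UnitRecord:
    sim = lcs_similarity(ref, cand)
    if len(ref) > DIFF_SPAN_LIMIT or len(cand) > DIFF_SPAN_LIMIT:
        return UnitRecord(ref_id, cand_id, sim, diffs=[], diff_truncated=True)
    return UnitRecord(ref_id, cand_id, sim, diffs=diff_spans(ref, cand))


def _paragraph_units(collection: dict) -> list[tuple[str, str]]:
    units = []
    for doc in collection.get("documents", []):
        for i, passage in enumerate(doc.get("passages", [])):
            units.append((f"{doc.get('id', '?')}/passage[{i}]", passage["text"]))
    return units


def _cell_units(table_json: dict) -> list[tuple[str, str]]:
    units = []
    doc_id = table_json.get("id", "?")
    for table in table_json.get("tables", []):
        ident = table["identifier"]
        for header in table.get("column_headers", []):
            units.append((f"{doc_id}/T{ident}/{header['cell_id']}", header["text"]))
        for section in table.get("sections", []):
            for row in section["rows"]:
                for cell in row:
                    value = cell["value"]
                    text = (
                        value
                        if isinstance(value, str)
                        else json.dumps(value)
                    )
                    units.append((f"{doc_id}/T{ident}/{cell['cell_id']}", text))
    return units


def compare_outputs(
    reference: dict, candidate: dict, granularity: str = "paragraph"
) -> SimilarityReport:
    """Pairwise unit comparison of two BioC collections (``paragraph``) or
    two table JSON objects (``cell``), paired by order within matching
    identifiers.

    Raises ``PairingError`` naming the first unpairable unit when the inputs
    are structurally incomparable (unequal unit counts).
    """
    if granularity == "paragraph":
        ref_units = _paragraph_units(reference)
        cand_units = _paragraph_units(candidate)
    elif granularity == "cell":
        ref_units = _cell_units(reference)
        cand_units = _cell_units(candidate)
    else:
        raise ValueError(f"unknown granularity {granularity!r}")
    if len(ref_units) != len(cand_units):
        longer = ref_units if len(ref_units) > len(cand_units) else cand_units
        first_odd = longer[min(len(ref_units), len(cand_units))][0]
        raise PairingError(
            f"unit counts differ ({len(ref_units)} reference vs "
            f"{len(cand_units)} candidate); first unpairable unit: {first_odd}"
        )
    report = SimilarityReport(granularity=granularity)
    for (rid, rtext), (cid, ctext) in zip(ref_units, cand_units):
        report.records.append(_unit_record(rid, cid, rtext, ctext))
    return report
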