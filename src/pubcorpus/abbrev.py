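"""Abbreviation/definition extraction.

Two detectors feed one merged output with per-method provenance:

* ``fulltext_bracket`` — the bracket-matching rule over running text: a
  parenthesized span with at least two non-digit characters is a short-form
  candidate; its definition is searched in a bounded window of words on
  either side of the brackets. The definition must start at a word whose
  first character equals the short form's first character
  (case-insensitively) and the remaining short-form characters must occur in
  order in the following text (hyphens are transparent).
* ``abbreviations_section`` — a dedicated abbreviations section
  (IAO:0000606) split into pairs on the section's dominant delimiter.

One-sided entries are never stored. The same short form may map to several
long forms, each keeping its own method list.
"""

from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

from ._schema import load_packaged_schema, validate_json

__all__ = [
    "AbbreviationSet",
    "METHOD_FULLTEXT",
    "METHOD_SECTION",
    "extract_inline",
    "parse_abbrev_section",
    "merge_abbreviations",
    "write_abbreviations",
    "read_abbreviations",
    "AbbrevWarning",
]

METHOD_FULLTEXT = "fulltext_bracket"
METHOD_SECTION = "abbreviations_section"

_WORD = re.compile(r"\S+")
# innermost parenthesized spans only
_INNER_BRACKET = re.compile(r"\(([^()]*)\)")


class AbbrevWarning(UserWarning):
    pass


@dataclass
class AbbreviationSet:
    """short form -> long form -> ordered, duplicate-free method list."""

    entries: dict[str, dict[str, list[str]]] = field(default_factory=dict)

    def add(self, short: str, long: str, method: str) -> None:
        if not short or not long:
            return  # one-sided definitions are never stored
        methods = self.entries.setdefault(short, {}).setdefault(long, [])
        if method not in methods:
            methods.append(method)

    def __len__(self) -> int:
        return len(self.entries)

    def to_dict(self) -> dict:
        return {
            short: {long: list(methods) for long, methods in sorted(longs.items())}
            for short, longs in sorted(self.entries.items())
        }

    @classmethod
    def from_dict(cls, data: dict) -> "AbbreviationSet":
        return cls(
            entries={
                short: {long: list(m) for long, m in longs.items()}
                for short, longs in data.items()
            }
        )


def _window(n_short: int) -> int:
    # Schwartz–Hearst convention for how far from the bracket a definition
    # may start
    return min(n_short + 5, 2 * n_short)


def _match_definition(words: list[str], short: str) -> str | None:
    """Try to read a definition for ``short`` from candidate words adjacent
    to the bracket (the bracket-adjacent word is ``words[-1]``).

    The definition starts at the rightmost word whose first character equals
    the short form's first character and whose span contains the remaining
    characters in order; the rightmost valid start yields the most compact
    definition.
    """
    first = short[0].lower()
    rest = [c.lower() for c in short[1:] if c.isalnum()]
    for start in range(len(words) - 1, -1, -1):
        if not words[start] or words[start][0].lower() != first:
            continue
        span = " ".join(words[start:])
        pos = 1  # skip the matched first character of the first word
        ok = True
        for ch in rest:
            found = span.lower().find(ch, pos)
            if found < 0:
                ok = False
                break
            pos = found + 1
        if ok:
            return span
    return None


def extract_inline(text: str) -> list[tuple[str, str]]:
    """Bracket-rule abbreviation pairs from one markup-free passage text.

    For each innermost parenthesized span holding >= 2 non-digit characters,
    the words to the left of the bracket are tried first, then the words to
    the right; the first successful side wins and at most one pair is emitted
    per bracket occurrence.
    """
    pairs: list[tuple[str, str]] = []
    for m in _INNER_BRACKET.finditer(text):
        short = m.group(1).strip()
        if sum(1 for c in short if not c.isdigit() and not c.isspace()) < 2:
            continue
        if not short or not short[0].isalnum():
            continue
        window = _window(len(short))
        left_words = _WORD.findall(text[: m.start()])[-window:]
        right_words = _WORD.findall(text[m.end():])[:window]
        long = _match_definition(left_words, short)
        if long is None and right_words:
            # symmetric scan on the right: candidate starts at the word just
            # after the bracket
            long = _match_definition_right(right_words, short)
        if long is not None:
            pairs.append((short, _clean_long(long)))
    return pairs


def _match_definition_right(words: list[str], short: str) -> str | None:
    first = short[0].lower()
    if not words or not words[0] or words[0][0].lower() != first:
        return None
    rest = [c.lower() for c in short[1:] if c.isalnum()]
    joined = " ".join(words)
    pos = 1
    for ch in rest:
        found = joined.lower().find(ch, pos)
        if found < 0:
            return None
        pos = found + 1
    # keep words up to the one containing the last matched character
    acc = 0
    for i, w in enumerate(words):
        acc += len(w)
        if acc >= pos:
            return " ".join(words[: i + 1])
        acc += 1  # separating space
    return joined


def _clean_long(long: str) -> str:
    return long.strip().strip(",;:").strip()


def parse_abbrev_section(passages: list[str]) -> list[tuple[str, str]]:
    """Short/long pairs from the text of an abbreviations section.

    Entries are separated by semicolons or line breaks; within an entry the
    short form is split from the definition on the dominant delimiter of the
    section (colon, equals or comma, in order of precedence on ties).
    Entries lacking either side are dropped; a section with no recognizable
    delimiter yields zero pairs and a warning.
    """
    text = "\n".join(p for p in passages if p)
    if not text.strip():
        return []
    entries = [e.strip() for e in re.split(r"[;\n]+", text) if e.strip()]
    delims = [":", "=", ","]
    counts = {d: sum(1 for e in entries if d in e) for d in delims}
    best = max(counts.values())
    if best == 0:
        warnings.warn(
            "abbreviations section has no recognizable delimiter",
            AbbrevWarning,
            stacklevel=2,
        )
        return []
    delim = next(d for d in delims if counts[d] == best)
    pairs = []
    for entry in entries:
        if delim not in entry:
            continue
        short, _, long = entry.partition(delim)
        short, long = short.strip(), long.strip()
        if short and long:
            pairs.append((short, long))
    return pairs


def merge_abbreviations(
    inline_pairs: list[tuple[str, str]],
    section_pairs: list[tuple[str, str]],
) -> AbbreviationSet:
    """Union of both detectors with per-method provenance.

    Identical (short, long) pairs union their method lists; the same short
    form with different long forms keeps distinct entries. Commutative and
    idempotent over its two inputs.
    """
    out = AbbreviationSet()
    for short, long in inline_pairs:
        out.add(short, long, METHOD_FULLTEXT)
    for short, long in section_pairs:
        out.add(short, long, METHOD_SECTION)
    return out


def write_abbreviations(
    abbrevs: AbbreviationSet, path: str | Path, document_id: str = "document"
) -> None:
    payload = {
        "id": document_id,
        "source": "pubcorpus",
        "key": "pubcorpus_abbreviations.key",
        "abbreviations": abbrevs.to_dict(),
    }
    validate_json(payload, load_packaged_schema("abbreviations"))
    Path(path).write_text(
        json.dumps(payload, indent=2, ensure_ascii=False), encoding="utf-8"
    )


def read_abbreviations(path: str | Path) -> tuple[str, AbbreviationSet]:
    data = json.loads(Path(path).read_text(encoding="utf-8"))
    validate_json(data, load_packaged_schema("abbreviations"))
    return data["id"], AbbreviationSet.from_dict(data["abbreviations"])
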