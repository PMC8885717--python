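"""Source configuration files: which HTML elements delimit headings, paragraphs
and table parts for one publisher dialect.

A configuration is a JSON document naming element selectors per role. Regular
expressions are allowed both for element names (full match) and for attribute
values (substring search), so one file can cover a family of journals whose
markup is similar but not identical. Unknown keys are rejected rather than
ignored so that typos in hand-written configs surface immediately.
"""

from __future__ import annotations

import json
import re
from enum import Enum
from pathlib import Path
from typing import Mapping

from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator

__all__ = [
    "SelectorScope",
    "Selector",
    "SourceConfig",
    "ConfigError",
    "load_config",
    "loads_config",
    "node_matches",
]


class ConfigError(ValueError):
    """Raised when a source configuration file is structurally invalid."""


class SelectorScope(str, Enum):
    HEADING = "heading"
    PARAGRAPH = "paragraph"
    TABLE_CONTAINER = "table_container"
    TABLE_TITLE = "table_title"
    TABLE_CAPTION = "table_caption"
    TABLE_FOOTER = "table_footer"
    LINKED_TABLE_MARKER = "linked_table_marker"


class Selector(BaseModel):
    """One rule naming an HTML element (optionally attribute-constrained) and
    the structural role its matches play."""

    model_config = ConfigDict(extra="forbid", frozen=True)

    element_name: str
    attribute_constraints: tuple[tuple[str, str], ...] = ()
    scope: SelectorScope

    @field_validator("element_name")
    @classmethod
    def _element_nonempty(cls, v: str) -> str:
        if not v:
            raise ValueError("element_name must be non-empty")
        _compile(v)
        return v

    @field_validator("attribute_constraints", mode="before")
    @classmethod
    def _coerce_constraints(cls, v):
        if isinstance(v, Mapping):
            v = sorted(v.items())
        return tuple((str(k), str(p)) for k, p in v)

    @model_validator(mode="after")
    def _constraints_compile(self) -> "Selector":
        for _, pattern in self.attribute_constraints:
            _compile(pattern)
        return self

    def matches(self, tag: str, attributes: Mapping[str, str]) -> bool:
        return node_matches(tag, attributes, self)


class TablesMode(str, Enum):
    INLINE = "inline"
    LINKED = "linked"
    BOTH = "both"


class SourceConfig(BaseModel):
    """Declarative description of one publisher's HTML dialect."""

    model_config = ConfigDict(extra="forbid", frozen=True)

    source_name: str
    selectors: tuple[Selector, ...]
    tables_mode: TablesMode = TablesMode.INLINE
    contributors: str = ""

    @model_validator(mode="after")
    def _required_roles(self) -> "SourceConfig":
        scopes = {s.scope for s in self.selectors}
        if SelectorScope.HEADING not in scopes:
            raise ValueError("config must define at least one heading selector")
        if SelectorScope.PARAGRAPH not in scopes:
            raise ValueError("config must define at least one paragraph selector")
        if self.tables_mode in (TablesMode.LINKED, TablesMode.BOTH):
            if SelectorScope.TABLE_CONTAINER not in scopes:
                raise ValueError(
                    "tables_mode=%s requires a table_container selector"
                    % self.tables_mode.value
                )
        return self

    def by_scope(self, scope: SelectorScope) -> tuple[Selector, ...]:
        return tuple(s for s in self.selectors if s.scope == scope)

    def to_json(self) -> str:
        return json.dumps(self.model_dump(mode="json"), indent=2, ensure_ascii=False)


def _compile(pattern: str) -> re.Pattern[str]:
    try:
        return re.compile(pattern)
    except re.error as exc:
        raise ValueError(f"invalid regular expression {pattern!r}: {exc}") from exc


def node_matches(tag: str, attributes: Mapping[str, str], selector: Selector) -> bool:
    """True iff ``tag`` full-matches the selector's element name and every
    attribute constraint is satisfied by substring (regex search) on the
    node's attribute value. Total and side-effect free."""
    if not _compile(selector.element_name).fullmatch(tag):
        return False
    for name, pattern in selector.attribute_constraints:
        value = attributes.get(name)
        if value is None or not _compile(pattern).search(value):
            return False
    return True


def loads_config(text: str, *, source: str = "<string>") -> SourceConfig:
    """Parse and validate a configuration from a JSON string."""
    try:
        raw = json.loads(text)
    except json.JSONDecodeError as exc:
        raise ConfigError(f"{source}: not well-formed JSON: {exc}") from exc
    try:
        return SourceConfig.model_validate(raw)
    except Exception as exc:  # pydantic ValidationError names the offending key
        raise ConfigError(f"{source}: {exc}") from exc


def load_config(path: str | Path) -> SourceConfig:
    """Load, validate and compile a source configuration file.

    Raises ``FileNotFoundError`` for a missing file and ``ConfigError`` (with
    the offending key or pattern in the message) for schema violations.
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    return loads_config(text, source=str(path))


def minimal_config(
    heading: str = "h2", paragraph: str = "p", source_name: str = "minimal"
) -> SourceConfig:
    """Smallest valid configuration: one heading and one paragraph selector."""
    return SourceConfig(
        source_name=source_name,
        selectors=(
            Selector(element_name=heading, scope=SelectorScope.HEADING),
            Selector(element_name=paragraph, scope=SelectorScope.PARAGRAPH),
        ),
    )
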