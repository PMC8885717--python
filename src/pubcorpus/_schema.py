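"""Validation of the packaged output schemas.

The shipped schemas use a small, stable subset of JSON Schema (type,
properties, required, additionalProperties, items, patternProperties, enum)
and this module implements exactly that subset, raising ``SchemaError`` with
a JSON-pointer-style path to the offending element.
"""

from __future__ import annotations

import json
import re
from functools import lru_cache
from pathlib import Path

try:
    from importlib.resources import files as _pkg_files
except ImportError:  # pragma: no cover
    _pkg_files = None

__all__ = ["SchemaError", "validate_json", "load_packaged_schema"]

_TYPES = {
    "object": dict,
    "array": list,
    "string": str,
    "number": (int, float),
    "integer": int,
    "boolean": bool,
    "null": type(None),
}


class SchemaError(ValueError):
    """An instance does not conform to a packaged schema."""


@lru_cache(maxsize=None)
def load_packaged_schema(name: str) -> "_FrozenSchema":
    path = _pkg_files("pubcorpus").joinpath(f"schemas/{name}.schema.json")
    return _FrozenSchema(json.loads(Path(str(path)).read_text(encoding="utf-8")))


class _FrozenSchema:
    def __init__(self, data: dict):
        self.data = data


def _type_ok(value, expected: str) -> bool:
    py = _TYPES[expected]
    if expected == "number" and isinstance(value, bool):
        return False
    if expected == "integer" and isinstance(value, bool):
        return False
    if expected == "integer" and isinstance(value, float):
        return float(value).is_integer()
    return isinstance(value, py)


def _validate(value, schema: dict, path: str) -> None:
    expected = schema.get("type")
    if expected is not None:
        allowed = [expected] if isinstance(expected, str) else list(expected)
        if not any(_type_ok(value, t) for t in allowed):
            raise SchemaError(
                f"{path or '/'}: expected type {'/'.join(allowed)}, "
                f"got {type(value).__name__}"
            )
    if "enum" in schema and value not in schema["enum"]:
        raise SchemaError(f"{path or '/'}: {value!r} not in enum {schema['enum']}")
    if isinstance(value, dict):
        props = schema.get("properties", {})
        patterns = schema.get("patternProperties", {})
        for key in schema.get("required", []):
            if key not in value:
                raise SchemaError(f"{path or '/'}: missing required key {key!r}")
        extra = schema.get("additionalProperties", True)
        for key, sub in value.items():
            child = f"{path}/{key}"
            if key in props:
                _validate(sub, props[key], child)
                continue
            pat = next((p for p in patterns if re.search(p, key)), None)
            if pat is not None:
                _validate(sub, patterns[pat], child)
                continue
            if extra is False:
                raise SchemaError(f"{child}: unexpected key")
            if isinstance(extra, dict):
                _validate(sub, extra, child)
    elif isinstance(value, list) and "items" in schema:
        for i, item in enumerate(value):
            _validate(item, schema["items"], f"{path}/{i}")


def validate_json(instance, schema: "_FrozenSchema | dict") -> None:
    """Raise ``SchemaError`` if ``instance`` violates ``schema``."""
    data = schema.data if isinstance(schema, _FrozenSchema) else schema
    _validate(instance, data, "")
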