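"""Minimal JSON-Schema (draft-07 subset) validator.

Covers exactly the keywords used by the packaged map-elements schema:
``type``, ``enum``, ``required``, ``properties``, ``additionalProperties``
(boolean form), ``items``, ``minItems``, ``minimum``, ``oneOf`` and local
``$ref`` into ``definitions``.  Errors carry JSON-pointer-like paths so a
failing element can be named precisely.
"""

from __future__ import annotations

from typing import Any

_TYPES = {
    "object": dict,
    "array": list,
    "string": str,
    "integer": int,
    "number": (int, float),
    "boolean": bool,
    "null": type(None),
}


def _check_type(value: Any, expected: str) -> bool:
    py = _TYPES[expected]
    if expected in ("integer", "number") and isinstance(value, bool):
        return False
    return isinstance(value, py)


def _resolve_ref(ref: str, root: dict) -> dict:
    if not ref.startswith("#/"):
        raise ValueError(f"only local $ref supported, got {ref!r}")
    node: Any = root
    for part in ref[2:].split("/"):
        node = node[part]
    return node


def _validate(value: Any, schema: dict, root: dict, path: str, errors: list[str]) -> None:
    if "$ref" in schema:
        _validate(value, _resolve_ref(schema["$ref"], root), root, path, errors)
        return
    if "oneOf" in schema:
        n_ok = 0
        sub_errors: list[list[str]] = []
        for sub in schema["oneOf"]:
            errs: list[str] = []
            _validate(value, sub, root, path, errs)
            if not errs:
                n_ok += 1
            sub_errors.append(errs)
        if n_ok != 1:
            detail = "; ".join(e[0] for e in sub_errors if e)
            errors.append(
                f"{path}: matched {n_ok} of {len(schema['oneOf'])} alternatives ({detail})"
            )
        return
    if "type" in schema and not _check_type(value, schema["type"]):
        errors.append(f"{path}: expected {schema['type']}, got {type(value).__name__}")
        return
    if "enum" in schema and value not in schema["enum"]:
        errors.append(f"{path}: {value!r} not in {schema['enum']}")
        return
    if isinstance(value, dict):
        for key in schema.get("required", []):
            if key not in value:
                errors.append(f"{path}: missing required key {key!r}")
        props = schema.get("properties", {})
        for key, sub in props.items():
            if key in value:
                _validate(value[key], sub, root, f"{path}/{key}", errors)
        if schema.get("additionalProperties") is False:
            for key in value:
                if key not in props:
                    errors.append(f"{path}: unexpected key {key!r}")
    elif isinstance(value, list):
        if "minItems" in schema and len(value) < schema["minItems"]:
            errors.append(f"{path}: fewer than {schema['minItems']} items")
        if "items" in schema:
            for i, item in enumerate(value):
                _validate(item, schema["items"], root, f"{path}/{i}", errors)
    elif isinstance(value, (int, float)) and not isinstance(value, bool):
        if "minimum" in schema and value < schema["minimum"]:
            errors.append(f"{path}: {value} below minimum {schema['minimum']}")


def validate(instance: Any, schema: dict) -> list[str]:
    """Validate ``instance`` against ``schema``; returns error messages."""
    errors: list[str] = []
    _validate(instance, schema, schema, "$", errors)
    return errors
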