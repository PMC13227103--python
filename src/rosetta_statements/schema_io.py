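"""Statement-type definition files (JSON/YAML).

The on-disk structure mirrors the statement-type editor: a label,
description and example sentences, a ``verb`` display label, a ``subject``
block and an ordered ``objects`` list, each with role, placeholder, pre,
post, required flag, constraint (kind + class or datatype, optional
pattern/min/max) and max_values (``null`` = unbounded).  Loading and saving
round-trip bit-exactly.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Union

import yaml

from .errors import SchemaError
from .model import (
    ConstraintSpec,
    PositionSpec,
    StatementTypeSchema,
    define_statement_type,
)


def _constraint_to_dict(c: ConstraintSpec) -> dict:
    out = {"kind": c.kind}
    if c.kind == "resource":
        out["class"] = c.value_class
    else:
        out["datatype"] = c.datatype
        if c.pattern is not None:
            out["pattern"] = c.pattern
        if c.minimum is not None:
            out["min"] = c.minimum
        if c.maximum is not None:
            out["max"] = c.maximum
    return out


def _constraint_from_dict(d: dict) -> ConstraintSpec:
    kind = d.get("kind")
    if kind == "resource":
        return ConstraintSpec.resource(d["class"])
    if kind == "literal":
        return ConstraintSpec.literal(d["datatype"], pattern=d.get("pattern"),
                                      minimum=d.get("min"),
                                      maximum=d.get("max"))
    raise SchemaError(f"unknown constraint kind {kind!r} in definition file")


def _position_to_dict(p: PositionSpec) -> dict:
    return {
        "role": p.role_label,
        "placeholder": p.placeholder_text,
        "pre": p.preposition_text,
        "post": p.postposition_text,
        "description": p.description,
        "required": p.required,
        "constraint": _constraint_to_dict(p.constraint),
        "max_values": p.max_values,
    }


def _position_from_dict(d: dict, required_default: bool = True) -> PositionSpec:
    return PositionSpec(
        role_label=d["role"],
        placeholder_text=d.get("placeholder", ""),
        preposition_text=d.get("pre", ""),
        postposition_text=d.get("post", ""),
        description=d.get("description", ""),
        required=d.get("required", required_default),
        constraint=_constraint_from_dict(d["constraint"]),
        max_values=d.get("max_values", 1),
    )


def schema_to_dict(schema: StatementTypeSchema) -> dict:
    return {
        "label": schema.label,
        "verb": schema.verb,
        "description": schema.description,
        "examples": list(schema.example_sentences),
        "subject": _position_to_dict(schema.subject_position),
        "objects": [_position_to_dict(p)
                    for p in sorted(schema.object_positions,
                                    key=lambda p: p.index)],
        "type_iri": schema.type_iri,
        "schema_iri": schema.schema_iri,
    }


def schema_from_dict(d: dict) -> StatementTypeSchema:
    schema = define_statement_type(
        label=d["label"],
        description=d.get("description", ""),
        examples=d.get("examples", ()),
        subject_spec=_position_from_dict(d["subject"]),
        object_specs=[_position_from_dict(o) for o in d.get("objects", [])],
        verb_display=(d.get("verb")
                      if d.get("verb") not in (None, d["label"]) else None),
    )
    # definition files may pin explicit IRIs (overriding slug defaults)
    if "type_iri" in d or "schema_iri" in d:
        from dataclasses import replace
        schema = replace(schema,
                         type_iri=d.get("type_iri", schema.type_iri),
                         schema_iri=d.get("schema_iri", schema.schema_iri))
    return schema


def save_schema(schema: StatementTypeSchema, path: Union[str, Path]) -> None:
    path = Path(path)
    d = schema_to_dict(schema)
    if path.suffix in (".yaml", ".yml"):
        text = yaml.safe_dump(d, sort_keys=False, allow_unicode=True)
    else:
        text = json.dumps(d, indent=2, ensure_ascii=False) + "\n"
    path.write_text(text, encoding="utf-8")


def load_schema(path: Union[str, Path]) -> StatementTypeSchema:
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    if path.suffix in (".yaml", ".yml"):
        d = yaml.safe_load(text)
    else:
        d = json.loads(text)
    if not isinstance(d, dict):
        raise SchemaError(f"{path}: not a statement-type definition")
    return schema_from_dict(d)
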