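"""Dynamic labels and dynamic mind-map patterns.

A *dynamic label* is a sentence template derived from a statement-type
schema: the subject slot, the verb, then the object slots in template order,
each wrapped in its position's preposition/postposition texts.  Rendering a
statement replaces slots with resource labels or literal lexical forms
verbatim; an empty optional slot disappears *together with* its pre/post
texts, so "This orange has a weight of 212.45 grams" and the same schema's
fully bound confidence-interval sentence both come out of one template.

Pre/post texts may *echo* another slot with ``{ROLE}`` — e.g. a closing
postposition `` {UNIT})`` repeats the bound unit after the upper confidence
bound, which is how the measurement template prints the unit twice while
each role occurs only once as a slot.

A *dynamic mind-map pattern* renders statements as labelled nodes around a
predicate node; resource nodes are shared (merged by IRI) across
statements, so several statements about the same entities combine into one
map.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

from .errors import RenderError
from .full import VersionRecord
from .model import (
    SchemaRegistry,
    StatementRecord,
    StatementTypeSchema,
    ValueBinding,
)

NEGATION_PREFIX = "It is not the case that "

_ECHO_RE = re.compile(r"\{([^{}]+)\}")


@dataclass(frozen=True)
class SlotSegment:
    """One slot of the template with its surrounding display texts."""

    role_label: str
    preposition_text: str = ""
    postposition_text: str = ""
    is_subject: bool = False


@dataclass(frozen=True)
class VerbSegment:
    text: str


Segment = Union[SlotSegment, VerbSegment]


@dataclass(frozen=True)
class DynamicLabelTemplate:
    """Ordered segments: subject slot first, then the verb, then object
    slots in schema index order; each role appears exactly once as a slot
    (echo references inside pre/post texts repeat values, not slots)."""

    type_iri: str
    segments: Tuple[Segment, ...]

    def to_string(self) -> str:
        """The template as a human-readable pattern string, role labels in
        place of values (echo braces are stripped)."""
        parts: List[str] = []
        first = True
        for seg in self.segments:
            if isinstance(seg, VerbSegment):
                parts.append(" " + seg.text)
            else:
                pre = _ECHO_RE.sub(r"\1", seg.preposition_text)
                post = _ECHO_RE.sub(r"\1", seg.postposition_text)
                chunk = pre + seg.role_label + post
                if first:
                    chunk = chunk.lstrip() if not pre else chunk
                parts.append(chunk)
            first = False
        return "".join(parts)


def derive_label_template(schema: StatementTypeSchema) -> DynamicLabelTemplate:
    """Derive the default dynamic label from a schema: subject slot, verb,
    then object slots in index order with their pre/post texts."""
    segments: List[Segment] = [
        SlotSegment(
            role_label=schema.subject_position.role_label,
            preposition_text=schema.subject_position.preposition_text,
            postposition_text=schema.subject_position.postposition_text,
            is_subject=True,
        ),
        VerbSegment(schema.verb),
    ]
    for p in sorted(schema.object_positions, key=lambda p: p.index):
        segments.append(SlotSegment(
            role_label=p.role_label,
            preposition_text=p.preposition_text,
            postposition_text=p.postposition_text,
        ))
    return DynamicLabelTemplate(type_iri=schema.type_iri,
                                segments=tuple(segments))


def join_values(texts: Sequence[str]) -> str:
    """Natural-language join: ``A``; ``A and B``; ``A, B, …, and Z``
    (serial comma)."""
    if not texts:
        return ""
    if len(texts) == 1:
        return texts[0]
    if len(texts) == 2:
        return f"{texts[0]} and {texts[1]}"
    return ", ".join(texts[:-1]) + ", and " + texts[-1]


def _slot_text(bindings: Sequence[ValueBinding]) -> str:
    ordered = sorted(bindings, key=lambda b: b.order_rank)
    return join_values([b.display_value() for b in ordered])


def render_label(
    template: DynamicLabelTemplate,
    statement: Union[StatementRecord, VersionRecord],
    schema: StatementTypeSchema,
) -> str:
    """Render a statement (or statement version) as a sentence.

    Literal lexical forms and resource labels appear verbatim; empty
    optional slots and their pre/post texts are omitted; multi-valued slots
    are joined with a serial comma and "and", in order-rank order; negated
    statements are prefixed with "It is not the case that ".  An empty
    *required* slot makes the statement unrenderable.
    """
    record = statement.record if isinstance(statement, VersionRecord) else statement
    if record.type_iri != template.type_iri:
        raise RenderError(
            f"statement of type {record.type_iri} rendered with a template "
            f"for {template.type_iri}")

    slot_values: Dict[str, str] = {}
    subject_role = schema.subject_position.role_label
    slot_values[subject_role] = _slot_text(record.subject_bindings)
    for p in schema.object_positions:
        vals = record.values(p.role_label)
        if vals:
            slot_values[p.role_label] = _slot_text(vals)
        elif p.required:
            raise RenderError(
                f"required position {p.role_label!r} is empty; the "
                "statement cannot be rendered")

    def expand(text: str) -> str:
        return _ECHO_RE.sub(lambda m: slot_values.get(m.group(1), ""), text)

    parts: List[str] = []
    for seg in template.segments:
        if isinstance(seg, VerbSegment):
            parts.append(" " + seg.text if parts else seg.text)
            continue
        value = slot_values.get(seg.role_label)
        if value is None:
            continue  # empty optional slot: pre/post texts vanish with it
        parts.append(expand(seg.preposition_text) + value
                     + expand(seg.postposition_text))
    sentence = "".join(parts)
    if record.negated:
        sentence = NEGATION_PREFIX + sentence
    return sentence


# ---------------------------------------------------------------------------
# mind maps
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MindMapNode:
    id: str
    label: str
    kind: str  # "predicate" | "resource" | "literal"


@dataclass(frozen=True)
class MindMapEdge:
    source: str  # predicate node id
    target: str
    label: str


@dataclass(frozen=True)
class MindMapPattern:
    """Node/edge view of one or more statements: one predicate node per
    statement, one node per bound value; resource nodes merge by IRI."""

    nodes: Tuple[MindMapNode, ...]
    edges: Tuple[MindMapEdge, ...]

    def to_json_dict(self) -> dict:
        return {
            "nodes": [vars(n) for n in self.nodes],
            "edges": [vars(e) for e in self.edges],
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_json_dict(), **kwargs)

    def to_dot(self) -> str:
        lines = ["graph mindmap {"]
        for n in self.nodes:
            shape = "ellipse" if n.kind == "predicate" else "box"
            lines.append(
                f'  "{n.id}" [label={json.dumps(n.label)}, shape={shape}];')
        for e in self.edges:
            lines.append(
                f'  "{e.source}" -- "{e.target}" [label={json.dumps(e.label)}];')
        lines.append("}")
        return "\n".join(lines)


def render_mindmap(
    statements: Sequence[Union[StatementRecord, VersionRecord]],
    registry: SchemaRegistry,
) -> MindMapPattern:
    """Build a combined mind-map pattern for a list of statements.

    Every statement contributes one predicate node (labelled with the verb)
    and labelled edges to each bound subject/object value.  Resources are
    deduplicated across statements by IRI; literals get one node per
    occurrence (statement-scoped identity).
    """
    nodes: Dict[str, MindMapNode] = {}
    edges: List[MindMapEdge] = []
    for stmt in statements:
        record = stmt.record if isinstance(stmt, VersionRecord) else stmt
        schema = registry.get(record.type_iri)
        if schema is None:
            raise RenderError(f"no schema registered for {record.type_iri}")
        pred_id = record.statement_iri
        nodes[pred_id] = MindMapNode(pred_id, schema.verb, "predicate")

        def add_value(b: ValueBinding, role: str):
            if b.is_resource:
                nid = b.resource_iri
                if nid not in nodes:
                    nodes[nid] = MindMapNode(
                        nid, b.resource_label or b.resource_iri, "resource")
            else:
                nid = f"{pred_id}#{role}#{b.order_rank}"
                nodes[nid] = MindMapNode(nid, b.display_value(), "literal")
            edges.append(MindMapEdge(pred_id, nid, role))

        for b in record.subject_bindings:
            add_value(b, schema.subject_position.role_label)
        for p in schema.object_positions:
            for b in record.values(p.role_label):
                add_value(b, p.role_label)
    return MindMapPattern(nodes=tuple(nodes.values()), edges=tuple(edges))
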