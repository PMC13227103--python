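"""Light-dialect RDF serialisation.

In the light dialect a statement is a single resource, typed into its
statement-type class, that links *directly* to its subject and object values
through a small family of numbered position properties:
``subject``, ``required[Literal]ObjectPosition<i>`` and
``optional[Literal]ObjectPosition<i>``, where ``<i>`` is the position's index
in template order (shared across the resource and literal families).  A
basic weight measurement therefore costs three slot-linking triples — one
subject link, one value link, one unit link — where reality-modelling
schemata of the same content need five or six.

The dialect has no order property: multiple values in one position repeat
the same numbered predicate, and parsing assigns order ranks by sorting the
values lexicographically for determinism.  Lossless ordering (and
versioning, per-position history, soft delete) needs the full dialect.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Dict, List, Optional, Tuple, Union

from rdflib import Graph, Literal, RDF, RDFS, URIRef
from rdflib.namespace import XSD

from .errors import GraphParseError
from .model import (
    ProvenanceMetadata,
    SchemaRegistry,
    StatementRecord,
    StatementTypeSchema,
    ValueBinding,
    check_record,
)
from .vocab import DEFAULT_VOCAB, RosettaVocabulary


def _binding_node(b: ValueBinding) -> Union[URIRef, Literal]:
    if b.is_resource:
        return URIRef(b.resource_iri)
    # normalize=False: the stored lexical form is authoritative (labels must
    # reproduce it verbatim; round-trips must be exact)
    return Literal(b.lexical, datatype=URIRef(b.datatype), normalize=False)


def _add_resource_annotations(g: Graph, b: ValueBinding) -> None:
    if not b.is_resource:
        return
    node = URIRef(b.resource_iri)
    if b.resource_label is not None:
        g.add((node, RDFS.label, Literal(b.resource_label)))
    if b.resource_class is not None:
        g.add((node, RDF.type, URIRef(b.resource_class)))


def to_light_graph(
    record: StatementRecord,
    schema: StatementTypeSchema,
    vocab: RosettaVocabulary = DEFAULT_VOCAB,
) -> Graph:
    """Serialize a statement record to a light-dialect graph.

    Emits one ``rdf:type`` triple into the statement-type class (plus one
    into the negation class for negated statements), one ``subject`` triple
    per subject binding, and one numbered object-position triple per object
    binding.  Resource values additionally carry their label and class;
    provenance metadata attaches directly to the statement resource.
    """
    check_record(schema, record)
    g = Graph()
    g.bind("rosetta", vocab.namespace)
    g.bind("xsd", XSD)
    stmt = URIRef(record.statement_iri)
    g.add((stmt, RDF.type, URIRef(record.type_iri)))
    if record.negated:
        g.add((stmt, RDF.type, vocab.Negation))
    for b in record.subject_bindings:
        g.add((stmt, vocab.subject, _binding_node(b)))
        _add_resource_annotations(g, b)
    for p in schema.object_positions:
        pred = vocab.position_property(
            p.required, p.constraint.kind == "literal", p.index)
        for b in record.values(p.role_label):
            g.add((stmt, pred, _binding_node(b)))
            _add_resource_annotations(g, b)
    _add_metadata(g, stmt, record, vocab)
    return g


def _add_metadata(g: Graph, stmt: URIRef, record: StatementRecord,
                  vocab: RosettaVocabulary) -> None:
    m = record.provenance
    if record.certainty is not None:
        g.add((stmt, vocab.certainty,
               Literal(str(record.certainty), datatype=XSD.decimal)))
    if record.context_iri is not None:
        g.add((stmt, vocab.hasContext, URIRef(record.context_iri)))
    pairs = (
        (vocab.creator, m.creator),
        (vocab.author, m.author),
        (vocab.extractionMethod, m.extraction_method),
        (vocab.importedFrom, m.imported_from),
        (vocab.deletedBy, m.deleted_by),
    )
    for pred, val in pairs:
        if val is not None:
            g.add((stmt, pred, Literal(val)))
    if m.created_at is not None:
        g.add((stmt, vocab.createdAt,
               Literal(m.created_at, datatype=XSD.dateTime)))
    if m.deleted_at is not None:
        g.add((stmt, vocab.deletedAt,
               Literal(m.deleted_at, datatype=XSD.dateTime)))
    if m.modifiable is not True:
        g.add((stmt, vocab.modifiable,
               Literal("false", datatype=XSD.boolean)))


def _sort_key(node: Union[URIRef, Literal]) -> Tuple[int, str]:
    return (0 if isinstance(node, URIRef) else 1, str(node))


def find_statement_nodes(
    graph: Graph, registry: SchemaRegistry
) -> List[Tuple[URIRef, StatementTypeSchema]]:
    """All resources in ``graph`` typed into a registered statement class."""
    out = []
    for s, o in sorted(graph.subject_objects(RDF.type),
                       key=lambda p: (str(p[0]), str(p[1]))):
        schema = registry.get(str(o))
        if schema is not None:
            out.append((s, schema))
    return out


def from_light_graph(
    graph: Graph,
    registry: SchemaRegistry,
    statement_iri: Optional[str] = None,
    vocab: RosettaVocabulary = DEFAULT_VOCAB,
) -> StatementRecord:
    """Parse one statement back out of a light-dialect graph.

    Exact inverse of :func:`to_light_graph` up to the order of multiple
    values in one position (order ranks are reassigned by lexicographic
    sort — the light dialect does not represent order).
    """
    candidates = find_statement_nodes(graph, registry)
    if statement_iri is not None:
        candidates = [(s, sch) for s, sch in candidates
                      if str(s) == statement_iri]
    if not candidates:
        raise GraphParseError(
            "no resource in the graph is typed into a registered "
            "statement-type class")
    stmt, schema = candidates[0]

    subject_nodes: List[Union[URIRef, Literal]] = []
    by_index: Dict[int, List[Union[URIRef, Literal]]] = {}
    negated = False
    certainty = None
    context_iri = None
    meta: Dict[str, Optional[str]] = {}
    modifiable = True

    for pred, obj in graph.predicate_objects(stmt):
        if pred == RDF.type:
            if obj == vocab.Negation:
                negated = True
            elif str(obj) != schema.type_iri:
                raise GraphParseError(
                    f"statement {stmt} typed into unknown class {obj}")
            continue
        if pred == vocab.subject:
            subject_nodes.append(obj)
            continue
        info = vocab.decode_position_property(pred)
        if info is not None:
            if info.index is None:
                raise GraphParseError(
                    f"unnumbered position property {pred} is not part of "
                    "the light dialect")
            try:
                pos = schema.position_by_index(info.index)
            except Exception:
                raise GraphParseError(
                    f"object-position predicate {pred} has index "
                    f"{info.index} but the schema defines only "
                    f"{len(schema.object_positions)} positions") from None
            want_literal = pos.constraint.kind == "literal"
            if info.literal != want_literal or info.required != pos.required:
                raise GraphParseError(
                    f"predicate {pred} does not match position "
                    f"{pos.role_label!r} (required={pos.required}, "
                    f"kind={pos.constraint.kind})")
            by_index.setdefault(info.index, []).append(obj)
            continue
        if pred == vocab.certainty:
            certainty = float(obj)
        elif pred == vocab.hasContext:
            context_iri = str(obj)
        elif pred == vocab.creator:
            meta["creator"] = str(obj)
        elif pred == vocab.createdAt:
            meta["created_at"] = str(obj)
        elif pred == vocab.author:
            meta["author"] = str(obj)
        elif pred == vocab.extractionMethod:
            meta["extraction_method"] = str(obj)
        elif pred == vocab.importedFrom:
            meta["imported_from"] = str(obj)
        elif pred == vocab.deletedAt:
            meta["deleted_at"] = str(obj)
        elif pred == vocab.deletedBy:
            meta["deleted_by"] = str(obj)
        elif pred == vocab.modifiable:
            modifiable = str(obj) in ("true", "1")

    def to_binding(node, rank):
        if isinstance(node, URIRef):
            label = graph.value(node, RDFS.label)
            klass = None
            for t in sorted(graph.objects(node, RDF.type), key=str):
                klass = str(t)
                break
            return ValueBinding.resource(
                str(node), str(label) if label is not None else None,
                resource_class=klass, order_rank=rank)
        return ValueBinding.literal(str(node), str(node.datatype),
                                    order_rank=rank)

    subjects = tuple(
        to_binding(n, i)
        for i, n in enumerate(sorted(subject_nodes, key=_sort_key), start=1))
    bindings = {}
    for index, nodes in by_index.items():
        role = schema.position_by_index(index).role_label
        bindings[role] = tuple(
            to_binding(n, i)
            for i, n in enumerate(sorted(nodes, key=_sort_key), start=1))

    record = StatementRecord(
        statement_iri=str(stmt),
        type_iri=schema.type_iri,
        subject_bindings=subjects,
        bindings=bindings,
        negated=negated,
        certainty=certainty,
        context_iri=context_iri,
        provenance=ProvenanceMetadata(modifiable=modifiable, **meta),
    )
    check_record(schema, record)
    return record


def canonicalize_value_order(record: StatementRecord) -> StatementRecord:
    """Re-rank every multi-valued position lexicographically by value.

    This is the order :func:`from_light_graph` assigns, so
    ``from_light_graph(to_light_graph(s)) == canonicalize_value_order(s)``
    holds exactly; for records whose values are already in lexicographic
    order the round-trip is the identity.  The full dialect preserves order
    losslessly and does not need this."""
    def rerank(bindings):
        keyed = sorted(bindings,
                       key=lambda b: (0, b.resource_iri) if b.is_resource
                       else (1, b.lexical))
        return tuple(replace(b, order_rank=i)
                     for i, b in enumerate(keyed, start=1))

    return replace(
        record,
        subject_bindings=rerank(record.subject_bindings),
        bindings={role: rerank(vals)
                  for role, vals in record.bindings.items()},
    )


def count_slot_triples(
    graph: Graph,
    statement_iri: str,
    vocab: RosettaVocabulary = DEFAULT_VOCAB,
) -> int:
    """Number of slot-linking triples of a statement: triples whose subject
    is the statement and whose predicate is ``subject`` or a member of the
    numbered object-position property families.  ``rdf:type`` and metadata
    triples are excluded."""
    stmt = URIRef(statement_iri)
    n = 0
    for pred, _obj in graph.predicate_objects(stmt):
        if pred == vocab.subject:
            n += 1
        else:
            info = vocab.decode_position_property(pred)
            if info is not None and info.index is not None:
                n += 1
    return n


def canonical_turtle(graph: Graph) -> str:
    """Deterministic serialisation: one sorted N-Triples-style line per
    triple (a syntactic subset of Turtle), suitable for byte-stable diffs."""
    lines = sorted(
        f"{s.n3()} {p.n3()} {o.n3()} ." for s, p, o in graph
    )
    return "\n".join(lines) + ("\n" if lines else "")
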