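"""Slot-form query generation and faceted exploration.

Because all statement types share one metamodel, a form whose input fields
are the slots of a chosen statement type can be translated mechanically
into SPARQL: one graph pattern per filtered role, with filters for exact
resources, resource classes, literal equality and numeric/date ranges.
Queries against the full dialect resolve anchors to their current
(highest-numbered, non-deleted) version only.

The in-memory :class:`StatementStore` keeps both the typed records and the
merged RDF graph, so generated queries can be executed directly and audited
against the records.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

from rdflib import Graph, Literal, RDF, RDFS, URIRef
from rdflib.namespace import XSD

from .errors import QueryError
from .full import AnchorRecord, resolve_current, to_full_graph
from .light import to_light_graph
from .model import (
    SchemaRegistry,
    StatementRecord,
    StatementTypeSchema,
    ValueBinding,
)
from .vocab import DEFAULT_VOCAB, RosettaVocabulary


@dataclass(frozen=True)
class SlotFilter:
    """Filter on one slot: ``exact`` (resource IRI or literal value),
    ``class`` (resource must instantiate the class or an asserted
    subclass), or ``range`` (numeric/date lower and upper bounds,
    inclusive; either may be None)."""

    kind: str  # "exact" | "class" | "range"
    value: Optional[str] = None
    datatype: Optional[str] = None  # XSD IRI for literal equality
    low: Optional[float] = None
    high: Optional[float] = None

    @classmethod
    def exact_resource(cls, iri: str) -> "SlotFilter":
        return cls(kind="exact", value=iri)

    @classmethod
    def exact_literal(cls, lexical: str, datatype: str) -> "SlotFilter":
        return cls(kind="exact", value=lexical, datatype=datatype)

    @classmethod
    def value_class(cls, class_iri: str) -> "SlotFilter":
        return cls(kind="class", value=class_iri)

    @classmethod
    def in_range(cls, low: Optional[float], high: Optional[float]) -> "SlotFilter":
        return cls(kind="range", low=low, high=high)


@dataclass(frozen=True)
class SlotQuery:
    """A filled slot form: the statement type plus per-role filters
    (roles absent from ``filters`` are unconstrained).  The subject slot is
    addressed by its role label like any other."""

    type_iri: str
    filters: Dict[str, SlotFilter] = field(default_factory=dict)
    dialect: str = "full"


def _var(role: str) -> str:
    return "v_" + "".join(ch if ch.isalnum() else "_" for ch in role.lower())


def _filter_clause(var: str, f: SlotFilter, position, role: str) -> Tuple[str, List[str]]:
    """(value pattern suffix, FILTER lines) for one filtered slot."""
    c = position.constraint
    lines: List[str] = []
    if f.kind == "exact":
        if c.kind == "resource":
            if f.datatype:
                raise QueryError(
                    f"literal filter on resource position {role!r}")
            return f"<{f.value}>", []
        dt = f.datatype or c.datatype_iri
        return f'"{f.value}"^^<{dt}>', []
    if f.kind == "class":
        if c.kind != "resource":
            raise QueryError(f"class filter on literal position {role!r}")
        lines.append(
            f"?{var} <{RDF.type}>/<{RDFS.subClassOf}>* <{f.value}> .")
        return f"?{var}", lines
    if f.kind == "range":
        if c.kind != "literal":
            raise QueryError(f"range filter on resource position {role!r}")
        conds = []
        if f.low is not None:
            conds.append(f"?{var} >= {f.low}")
        if f.high is not None:
            conds.append(f"?{var} <= {f.high}")
        if conds:
            lines.append(f"FILTER ({' && '.join(conds)})")
        return f"?{var}", lines
    raise QueryError(f"unknown filter kind {f.kind!r}")


def build_query(
    query: SlotQuery,
    schema: StatementTypeSchema,
    vocab: RosettaVocabulary = DEFAULT_VOCAB,
) -> str:
    """Translate a filled slot form into a SPARQL SELECT query.

    Light dialect: selects statement resources.  Full dialect: selects
    anchors with their current version (non-deleted anchors, non-deleted
    versions, highest version number), so query results always reflect the
    statement's newest accepted content.
    """
    if query.type_iri != schema.type_iri:
        raise QueryError(
            f"query type {query.type_iri} does not match schema "
            f"{schema.type_iri}")
    subject_role = schema.subject_position.role_label
    for role in query.filters:
        schema.position(role)  # raises UnknownRoleError

    lines: List[str] = []
    if query.dialect == "light":
        lines.append("SELECT DISTINCT ?stmt WHERE {")
        lines.append(f"  ?stmt a <{schema.type_iri}> .")
        # anchors and versions also instantiate the type class
        lines.append(f"  FILTER NOT EXISTS {{ ?stmt <{vocab.hasVersion}> ?hv . }}")
        lines.append(
            f"  FILTER NOT EXISTS {{ ?stmt <{vocab.versionNumber}> ?svn . }}")
        for role, f in sorted(query.filters.items()):
            pos = schema.position(role)
            var = _var(role)
            term, extra = _filter_clause(var, f, pos, role)
            if role == subject_role:
                pred = vocab.subject
            else:
                pred = vocab.position_property(
                    pos.required, pos.constraint.kind == "literal", pos.index)
            lines.append(f"  ?stmt <{pred}> {term} .")
            lines.extend(f"  {x}" for x in extra)
        lines.append("}")
        return "\n".join(lines)

    if query.dialect != "full":
        raise QueryError(f"unknown dialect {query.dialect!r}")
    lines.append("SELECT DISTINCT ?anchor ?version WHERE {")
    lines.append(f"  ?anchor a <{schema.type_iri}> ;")
    lines.append(f"      <{vocab.hasVersion}> ?version .")
    lines.append(f"  ?version <{vocab.versionNumber}> ?vn .")
    lines.append(f"  FILTER NOT EXISTS {{ ?anchor <{vocab.deletedAt}> ?adel . }}")
    lines.append(f"  FILTER NOT EXISTS {{ ?version <{vocab.deletedAt}> ?vdel . }}")
    lines.append("  FILTER NOT EXISTS {")
    lines.append(f"    ?anchor <{vocab.hasVersion}> ?other .")
    lines.append(f"    ?other <{vocab.versionNumber}> ?on .")
    lines.append(f"    FILTER NOT EXISTS {{ ?other <{vocab.deletedAt}> ?odel . }}")
    lines.append("    FILTER (?on > ?vn)")
    lines.append("  }")
    for role, f in sorted(query.filters.items()):
        pos = schema.position(role)
        var = _var(role)
        term, extra = _filter_clause(var, f, pos, role)
        inst = f"?p_{var}"
        if role == subject_role:
            lines.append(f"  ?version <{vocab.subject}> {inst} .")
            lines.append(f"  {inst} a <{vocab.SubjectPosition}> ;")
        else:
            link = vocab.position_property(pos.required, literal=False)
            pos_class = schema.position_class_iri(role)
            lines.append(f"  ?version <{link}> {inst} .")
            lines.append(f"  {inst} a <{pos_class}> ;")
        lines.append(f"      <{RDF.value}> {term} .")
        lines.extend(f"  {x}" for x in extra)
    lines.append("}")
    return "\n".join(lines)


# ---------------------------------------------------------------------------
# store
# ---------------------------------------------------------------------------

class StatementStore:
    """In-memory store of statements plus the merged RDF graph they
    serialize to.  Light records and full anchors can be mixed; an ontology
    graph (class hierarchy and labels) may be loaded for class filters and
    facet labelling."""

    def __init__(self, registry: SchemaRegistry,
                 vocab: RosettaVocabulary = DEFAULT_VOCAB):
        self.registry = registry
        self.vocab = vocab
        self.records: List[StatementRecord] = []
        self.anchors: List[AnchorRecord] = []
        self.graph = Graph()

    def add_record(self, record: StatementRecord) -> None:
        schema = self.registry.get(record.type_iri)
        if schema is None:
            raise QueryError(f"no schema registered for {record.type_iri}")
        self.records.append(record)
        self.graph += to_light_graph(record, schema, self.vocab)

    def add_anchor(self, anchor: AnchorRecord) -> None:
        schema = self.registry.get(anchor.type_iri)
        if schema is None:
            raise QueryError(f"no schema registered for {anchor.type_iri}")
        self.anchors.append(anchor)
        self.graph += to_full_graph(anchor, schema, self.vocab)

    def load_ontology(self, graph: Graph) -> None:
        self.graph += graph

    def run(self, sparql: str):
        return self.graph.query(sparql)

    def run_slot_query(self, query: SlotQuery) -> List[str]:
        """Execute a slot query; returns statement IRIs (light) or anchor
        IRIs (full), sorted."""
        schema = self.registry.get(query.type_iri)
        if schema is None:
            raise QueryError(f"no schema registered for {query.type_iri}")
        res = self.run(build_query(query, schema, self.vocab))
        return sorted(str(row[0]) for row in res)


def _facet_key(graph: Graph, binding_node, vocab) -> str:
    """Facet key of one bound value: a resource's label where asserted
    (instances of one kind that share a label — e.g. several apples — fall
    into one facet bucket), else its IRI local name; literals by lexical
    form."""
    if isinstance(binding_node, Literal):
        return str(binding_node)
    label = graph.value(binding_node, RDFS.label)
    if label is not None:
        return str(label)
    s = str(binding_node)
    return s.rsplit("/", 1)[-1].rsplit("#", 1)[-1]


def facet_counts(
    store: StatementStore,
    type_iri: str,
    dialect: str = "full",
) -> Dict[str, Dict[str, int]]:
    """Per-role value counts over all statements of a type, computed from
    the RDF graph.  Each bound value counts once per statement; for the
    full dialect only current (non-deleted) versions are tallied."""
    schema = store.registry.get(type_iri)
    if schema is None:
        raise QueryError(f"no schema registered for {type_iri}")
    vocab = store.vocab
    g = store.graph
    counts: Dict[str, Counter] = {
        schema.subject_position.role_label: Counter()}
    for p in schema.object_positions:
        counts[p.role_label] = Counter()

    if dialect == "light":
        stmts = [s for s in g.subjects(RDF.type, URIRef(type_iri))
                 if (s, vocab.hasVersion, None) not in g
                 and (s, vocab.versionNumber, None) not in g]
        for stmt in stmts:
            for obj in g.objects(stmt, vocab.subject):
                counts[schema.subject_position.role_label][
                    _facet_key(g, obj, vocab)] += 1
            for p in schema.object_positions:
                pred = vocab.position_property(
                    p.required, p.constraint.kind == "literal", p.index)
                for obj in g.objects(stmt, pred):
                    counts[p.role_label][_facet_key(g, obj, vocab)] += 1
    else:
        anchors = [s for s in g.subjects(RDF.type, URIRef(type_iri))
                   if (s, vocab.hasVersion, None) in g
                   and (s, vocab.deletedAt, None) not in g]
        for a in anchors:
            current, best = None, 0
            for v in g.objects(a, vocab.hasVersion):
                if (v, vocab.deletedAt, None) in g:
                    continue
                n = int(g.value(v, vocab.versionNumber))
                if n > best:
                    current, best = v, n
            if current is None:
                continue
            for inst in g.objects(current, vocab.subject):
                counts[schema.subject_position.role_label][
                    _facet_key(g, g.value(inst, RDF.value), vocab)] += 1
            for link in (vocab.position_property(True, literal=False),
                         vocab.position_property(False, literal=False),
                         vocab.hasObjectPosition):
                for inst in g.objects(current, link):
                    role = None
                    for t in g.objects(inst, RDF.type):
                        role = schema.role_for_position_class(str(t))
                        if role:
                            break
                    if role:
                        counts[role][_facet_key(
                            g, g.value(inst, RDF.value), vocab)] += 1
    return {role: dict(c) for role, c in counts.items()}
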