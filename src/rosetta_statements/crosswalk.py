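"""Declarative schema cross-walks.

A statement schema is optimized for human-facing capture; other schemata
are optimized for reasoning (OBI/OBOE-style measurement models) or for
tabular tooling.  A cross-walk maps the slots of one statement type onto a
target structure: intermediate nodes (measurement datum, value
specification, observation, measurement), a triple pattern over those
nodes, and an *entity map* translating resource IRIs between vocabularies
(e.g. a general-vocabulary ``gram`` into a units-ontology ``gram``) so the
target schema's constraints are satisfied.

Graph targets are emitted inside a named graph whose IRI is the statement
resource, keeping the statement referencable from the target side; the
tabular target instead carries the statement IRI in a dedicated column.

Triple templates reference their terms symbolically:

=================  ====================================================
``statement``      the statement IRI
``subject``        the (first) subject resource, entity-mapped if mapped
``role:R``         the value bound in position R (mapped if a resource)
``node:NAME``      an intermediate node minted per statement
``iri:<IRI>``      a constant IRI
``literal:<text>`` a constant literal
=================  ====================================================
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

from rdflib import Graph, Literal, RDF, URIRef

from .errors import CrosswalkError, UnmappedEntityError
from .model import StatementRecord, StatementTypeSchema, ValueBinding
from .vocab import DEFAULT_VOCAB

# vocabularies used by the built-in measurement cross-walks
OBO = "http://purl.obolibrary.org/obo/"
OBOE = "http://ecoinformatics.org/oboe/oboe.1.2/oboe-core.owl#"

IS_QUALITY_MEASUREMENT_OF = OBO + "IAO_0000221"
INHERES_IN = OBO + "RO_0000052"
HAS_VALUE_SPECIFICATION = OBO + "OBI_0001938"
HAS_SPECIFIED_NUMERIC_VALUE = OBO + "OBI_0001937"
HAS_MEASUREMENT_UNIT_LABEL = OBO + "IAO_0000039"
SCALAR_MEASUREMENT_DATUM = OBO + "IAO_0000032"
SCALAR_VALUE_SPECIFICATION = OBO + "OBI_0001931"


@dataclass(frozen=True)
class CrosswalkSpec:
    """Declarative mapping from one statement type to a target schema.

    ``target`` names the flavour (``obi-style``, ``oboe-style``,
    ``tabular``, ``custom``); ``nodes`` mints intermediate nodes (name ->
    class IRI or None); ``triples`` is the symbolic triple pattern for graph
    targets; ``columns`` the ordered (name, ref) pairs for the tabular
    target.  ``entity_map`` translates resource IRIs; roles listed in
    ``mapped_roles`` *must* have a translation for each bound resource.
    """

    source_type_iri: str
    target: str
    nodes: Mapping[str, Optional[str]] = field(default_factory=dict)
    triples: Tuple[Tuple[str, str, str], ...] = ()
    columns: Tuple[Tuple[str, str], ...] = ()
    entity_map: Mapping[str, str] = field(default_factory=dict)
    mapped_roles: Tuple[str, ...] = ()

    def required_roles_covered(self, schema: StatementTypeSchema) -> List[str]:
        """Required roles of the schema not referenced by the spec."""
        refs = {r for t in self.triples for r in t} | \
               {ref for _n, ref in self.columns}
        covered = {ref[5:] for ref in refs if ref.startswith("role:")}
        return [p.role_label for p in schema.object_positions
                if p.required and p.role_label not in covered]


@dataclass
class CrosswalkResult:
    """Either a target graph (named by the statement IRI) or a table row."""

    statement_iri: str
    graph: Optional[Graph] = None
    row: Optional[Dict[str, str]] = None

    def to_trig(self) -> str:
        from rdflib import Dataset
        ds = Dataset()
        ctx = ds.graph(URIRef(self.statement_iri))
        for t in self.graph:
            ctx.add(t)
        return ds.serialize(format="trig")

    def to_turtle(self) -> str:
        return self.graph.serialize(format="turtle")


def slot_path_triple_count(graph: Graph) -> int:
    """Triples carrying slot content in a cross-walk output graph
    (``rdf:type`` node-classification triples excluded)."""
    return sum(1 for _s, p, _o in graph if p != RDF.type)


def _map_entity(spec: CrosswalkSpec, iri: str, role: str) -> str:
    if iri in spec.entity_map:
        return spec.entity_map[iri]
    if role in spec.mapped_roles:
        raise UnmappedEntityError(iri, role)
    return iri


def _first(vals: Sequence[ValueBinding], role: str) -> ValueBinding:
    if not vals:
        raise CrosswalkError(f"position {role!r} is unbound")
    return sorted(vals, key=lambda b: b.order_rank)[0]


def apply_crosswalk(
    record: StatementRecord,
    spec: CrosswalkSpec,
    schema: StatementTypeSchema,
) -> CrosswalkResult:
    """Apply a cross-walk to one statement.

    All bound values are preserved: every literal lexical form and every
    (entity-mapped) resource IRI of the source appears in the target.
    Raises when a required role is unmapped by the spec or an entity
    translation is missing for a role that requires one.
    """
    if record.type_iri != spec.source_type_iri:
        raise CrosswalkError(
            f"statement of type {record.type_iri} does not match cross-walk "
            f"source {spec.source_type_iri}")
    missing = spec.required_roles_covered(schema)
    if missing:
        raise CrosswalkError(
            f"cross-walk does not map required role(s): {', '.join(missing)}")

    def resolve(ref: str, node_iris: Dict[str, str]):
        if ref == "statement":
            return URIRef(record.statement_iri)
        if ref == "subject":
            b = _first(record.subject_bindings,
                       schema.subject_position.role_label)
            return URIRef(_map_entity(
                spec, b.resource_iri, schema.subject_position.role_label))
        if ref.startswith("role:"):
            role = ref[5:]
            b = _first(record.values(role), role)
            if b.is_resource:
                return URIRef(_map_entity(spec, b.resource_iri, role))
            return Literal(b.lexical, datatype=URIRef(b.datatype))
        if ref.startswith("node:"):
            return URIRef(node_iris[ref[5:]])
        if ref.startswith("iri:"):
            return URIRef(ref[4:])
        if ref.startswith("literal:"):
            return Literal(ref[8:])
        raise CrosswalkError(f"unknown term reference {ref!r}")

    if spec.target == "tabular":
        row: Dict[str, str] = {}
        for name, ref in spec.columns:
            if ref.startswith("role:") and not record.values(ref[5:]):
                row[name] = ""
                continue
            val = resolve(ref, {})
            if isinstance(val, Literal):
                row[name] = str(val)
            else:
                row[name] = str(val)
            # resources in a table are more useful as labels where known
            if ref == "subject":
                b = _first(record.subject_bindings, "subject")
                row[name] = b.resource_label or str(val)
            elif ref.startswith("role:"):
                b = _first(record.values(ref[5:]), ref)
                if b.is_resource and b.resource_label:
                    row[name] = b.resource_label
        return CrosswalkResult(statement_iri=record.statement_iri, row=row)

    node_iris = {name: f"{record.statement_iri}/{spec.target}/{name}"
                 for name in spec.nodes}
    g = Graph()
    g.bind("obo", OBO)
    g.bind("oboe", OBOE)
    for name, cls in spec.nodes.items():
        if cls is not None:
            g.add((URIRef(node_iris[name]), RDF.type, URIRef(cls)))
    for s_ref, p_iri, o_ref in spec.triples:
        g.add((resolve(s_ref, node_iris), URIRef(p_iri),
               resolve(o_ref, node_iris)))
    return CrosswalkResult(statement_iri=record.statement_iri, graph=g)


def extract_from_crosswalk(
    result: CrosswalkResult,
    spec: CrosswalkSpec,
    schema: StatementTypeSchema,
) -> Tuple[str, Dict[str, ValueBinding]]:
    """Invert a graph cross-walk: recover the subject IRI and the role ->
    value bindings from a target graph, applying the inverse entity map.
    Exact recovery requires a bijective entity map."""
    if result.graph is None:
        raise CrosswalkError("only graph targets can be inverted")
    inverse = {v: k for k, v in spec.entity_map.items()}
    if len(inverse) != len(spec.entity_map):
        raise CrosswalkError("entity map is not bijective")
    node_iris = {name: f"{result.statement_iri}/{spec.target}/{name}"
                 for name in spec.nodes}
    subject_iri = None
    bindings: Dict[str, ValueBinding] = {}
    for s_ref, p_iri, o_ref in spec.triples:
        subj_candidates = _match_term(result.graph, s_ref, p_iri, o_ref,
                                      node_iris, position="s")
        obj_candidates = _match_term(result.graph, s_ref, p_iri, o_ref,
                                     node_iris, position="o")
        for ref, values in (("s", subj_candidates), ("o", obj_candidates)):
            target_ref = s_ref if ref == "s" else o_ref
            if not values:
                raise CrosswalkError(
                    f"target graph is missing the pattern "
                    f"({s_ref}, {p_iri}, {o_ref})")
            val = values[0]
            if target_ref == "subject":
                subject_iri = inverse.get(str(val), str(val))
            elif target_ref.startswith("role:"):
                role = target_ref[5:]
                if isinstance(val, Literal):
                    bindings[role] = ValueBinding.literal(
                        str(val), str(val.datatype))
                else:
                    bindings[role] = ValueBinding.resource(
                        inverse.get(str(val), str(val)))
    if subject_iri is None:
        raise CrosswalkError("cross-walk pattern does not reference the "
                             "subject; cannot invert")
    return subject_iri, bindings


def _match_term(g: Graph, s_ref, p_iri, o_ref, node_iris, position):
    """Values occupying one end of a template triple in the target graph."""
    def anchor(ref):
        if ref.startswith("node:"):
            return URIRef(node_iris[ref[5:]])
        if ref.startswith("iri:"):
            return URIRef(ref[4:])
        if ref == "statement":
            return None  # unknown at extraction time in general
        return None

    s_fix = anchor(s_ref)
    o_fix = anchor(o_ref)
    out = []
    for s, _p, o in g.triples((s_fix, URIRef(p_iri), o_fix)):
        out.append(s if position == "s" else o)
    return out


# ---------------------------------------------------------------------------
# built-in measurement cross-walks
# ---------------------------------------------------------------------------

def obi_measurement_spec(
    schema: StatementTypeSchema,
    quality_class: str,
    entity_map: Mapping[str, str],
    *,
    value_role: str = "VALUE",
    unit_role: str = "UNIT",
) -> CrosswalkSpec:
    """OBI-style measurement pattern (5 slot-path triples): a scalar
    measurement datum is a quality measurement of a quality inhering in the
    subject, and has a scalar value specification carrying the numeric
    value and the unit.  The measured quality is fixed by the statement
    type and enters as the minted quality instance's class."""
    return CrosswalkSpec(
        source_type_iri=schema.type_iri,
        target="obi-style",
        nodes={
            "datum": SCALAR_MEASUREMENT_DATUM,
            "quality": quality_class,
            "valuespec": SCALAR_VALUE_SPECIFICATION,
        },
        triples=(
            ("node:datum", IS_QUALITY_MEASUREMENT_OF, "node:quality"),
            ("node:quality", INHERES_IN, "subject"),
            ("node:datum", HAS_VALUE_SPECIFICATION, "node:valuespec"),
            ("node:valuespec", HAS_SPECIFIED_NUMERIC_VALUE, f"role:{value_role}"),
            ("node:valuespec", HAS_MEASUREMENT_UNIT_LABEL, f"role:{unit_role}"),
        ),
        entity_map=dict(entity_map),
        mapped_roles=(unit_role,),
    )


def oboe_measurement_spec(
    schema: StatementTypeSchema,
    characteristic_class: str,
    entity_map: Mapping[str, str],
    *,
    value_role: str = "VALUE",
    unit_role: str = "UNIT",
) -> CrosswalkSpec:
    """OBOE-style observation pattern (6 slot-path triples): an observation
    of the subject entity has a measurement of a characteristic, whose
    value node carries the numeric value, against a measurement standard
    (the unit)."""
    return CrosswalkSpec(
        source_type_iri=schema.type_iri,
        target="oboe-style",
        nodes={
            "observation": OBOE + "Observation",
            "measurement": OBOE + "Measurement",
            "characteristic": characteristic_class,
            "value": None,
        },
        triples=(
            ("node:observation", OBOE + "ofEntity", "subject"),
            ("node:observation", OBOE + "hasMeasurement", "node:measurement"),
            ("node:measurement", OBOE + "ofCharacteristic", "node:characteristic"),
            ("node:measurement", OBOE + "hasValue", "node:value"),
            ("node:value", str(RDF.value), f"role:{value_role}"),
            ("node:measurement", OBOE + "usesStandard", f"role:{unit_role}"),
        ),
        entity_map=dict(entity_map),
        mapped_roles=(unit_role,),
    )


def tabular_measurement_spec(
    schema: StatementTypeSchema,
    quality_label: str,
    *,
    value_role: str = "VALUE",
    unit_role: str = "UNIT",
) -> CrosswalkSpec:
    """Relational-table target: the statement IRI occupies a dedicated
    column so statements stay referencable, then subject, the type-fixed
    quality, value and unit."""
    return CrosswalkSpec(
        source_type_iri=schema.type_iri,
        target="tabular",
        columns=(
            ("statement_iri", "statement"),
            ("subject", "subject"),
            ("quality", f"literal:{quality_label}"),
            ("value", f"role:{value_role}"),
            ("unit", f"role:{unit_role}"),
        ),
    )


def generic_tabular_spec(schema: StatementTypeSchema) -> CrosswalkSpec:
    """Default table layout for any statement type: statement IRI, subject,
    then the role labels in schema order."""
    cols = [("statement_iri", "statement"), ("subject", "subject")]
    for p in schema.object_positions:
        cols.append((p.role_label.lower().replace(" ", "_"),
                     f"role:{p.role_label}"))
    return CrosswalkSpec(source_type_iri=schema.type_iri, target="tabular",
                         columns=tuple(cols))


def rows_to_csv(columns: Sequence[str], rows: Sequence[Mapping[str, str]]) -> str:
    buf = io.StringIO()
    w = csv.DictWriter(buf, fieldnames=list(columns))
    w.writeheader()
    for r in rows:
        w.writerow({c: r.get(c, "") for c in columns})
    return buf.getvalue()
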