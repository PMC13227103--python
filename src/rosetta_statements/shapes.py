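"""SHACL shape generation and validation.

Every statement-type schema is mechanically translatable into a SHACL
shape — the shape IRI *is* the schema IRI, so the full dialect's ``has data
schema`` link resolves to a machine-checkable constraint specification.

Light dialect: one node shape targeting the statement-type class, with one
property shape per position (path = the numbered position property;
required -> ``sh:minCount 1``; bounded cardinality -> ``sh:maxCount``;
resource constraints -> ``sh:class``, literal constraints ->
``sh:datatype`` plus optional ``sh:pattern`` / ``sh:minInclusive`` /
``sh:maxInclusive``) plus one for the subject path.

Full dialect: the statement shape targets version resources (subjects of
``version number``); per-role cardinality is expressed with qualified value
shapes over the generic link properties, value constraints sit on
per-position node shapes targeting the object-position classes, and the
subject's value class is checked through the sequence path
``(subject, rdf:value)``.

Class constraints admit instances of the class or of any subclass *as
asserted in the data graph* (``rdfs:subClassOf`` closure; no reasoner is
invoked).  Shapes are open by default — a schema may later gain optional
adjunct positions without invalidating old data; a closed mode is available
behind a flag.

Validation is performed by an in-package interpreter of exactly this SHACL
fragment (targetClass / targetSubjectsOf, predicate and sequence paths,
min/max count, class, datatype, pattern, numeric ranges, qualified value
shapes, closedness).
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

from rdflib import BNode, Graph, Literal, Namespace, RDF, RDFS, URIRef
from rdflib.collection import Collection
from rdflib.namespace import SH, XSD

from .errors import RosettaError
from .model import StatementTypeSchema, validate_type_schema
from .vocab import DEFAULT_VOCAB, RosettaVocabulary


@dataclass(frozen=True)
class ShapeBundle:
    """A generated shape graph plus its entry points."""

    graph: Graph
    shape_iri: str
    target_class: str
    dialect: str  # "light" | "full"
    #: role label -> property shape IRI (the cardinality-bearing shape);
    #: the subject path is under the subject position's role label.
    position_shapes: Dict[str, str] = field(default_factory=dict)


def _property_shape_iri(schema_iri: str, role: str) -> URIRef:
    from .model import slugify
    return URIRef(f"{schema_iri}/property/{slugify(role)}")


def _add_value_constraints(g: Graph, pshape: URIRef, constraint) -> None:
    if constraint.kind == "resource":
        g.add((pshape, SH["class"], URIRef(constraint.value_class)))
    else:
        g.add((pshape, SH.datatype, URIRef(constraint.datatype_iri)))
        if constraint.pattern is not None:
            g.add((pshape, SH.pattern, Literal(constraint.pattern)))
        if constraint.minimum is not None:
            g.add((pshape, SH.minInclusive, Literal(constraint.minimum)))
        if constraint.maximum is not None:
            g.add((pshape, SH.maxInclusive, Literal(constraint.maximum)))


def _seq_path(g: Graph, *steps: URIRef) -> BNode:
    node = BNode()
    Collection(g, node, list(steps))
    return node


def generate_shape(
    schema: StatementTypeSchema,
    dialect: str = "light",
    vocab: RosettaVocabulary = DEFAULT_VOCAB,
    *,
    closed: bool = False,
) -> ShapeBundle:
    """Generate the SHACL shape of a statement type for one dialect."""
    issues = validate_type_schema(schema)
    if issues:
        raise RosettaError(
            f"cannot generate a shape for an invalid schema: "
            f"{issues[0].message}")
    if dialect not in ("light", "full"):
        raise RosettaError(f"unknown dialect {dialect!r}")
    g = Graph()
    g.bind("sh", SH)
    g.bind("rosetta", vocab.namespace)
    shape = URIRef(schema.schema_iri)
    g.add((shape, RDF.type, SH.NodeShape))
    g.add((shape, RDFS.label,
           Literal(f"data schema of statement type '{schema.label}'")))
    position_shapes: Dict[str, str] = {}
    subj = schema.subject_position

    if dialect == "light":
        g.add((shape, SH.targetClass, URIRef(schema.type_iri)))
        ps = _property_shape_iri(schema.schema_iri, subj.role_label)
        g.add((shape, SH.property, ps))
        g.add((ps, SH.path, vocab.subject))
        g.add((ps, SH.name, Literal(subj.role_label)))
        g.add((ps, SH.minCount, Literal(1)))
        if subj.max_values is not None:
            g.add((ps, SH.maxCount, Literal(subj.max_values)))
        _add_value_constraints(g, ps, subj.constraint)
        position_shapes[subj.role_label] = str(ps)
        for p in schema.object_positions:
            ps = _property_shape_iri(schema.schema_iri, p.role_label)
            g.add((shape, SH.property, ps))
            g.add((ps, SH.path, vocab.position_property(
                p.required, p.constraint.kind == "literal", p.index)))
            g.add((ps, SH.name, Literal(p.role_label)))
            g.add((ps, SH.minCount, Literal(1 if p.required else 0)))
            if p.max_values is not None:
                g.add((ps, SH.maxCount, Literal(p.max_values)))
            _add_value_constraints(g, ps, p.constraint)
            position_shapes[p.role_label] = str(ps)
        if closed:
            g.add((shape, SH.closed, Literal(True)))
            ignored = BNode()
            Collection(g, ignored, [
                RDF.type, vocab.certainty, vocab.hasContext, vocab.creator,
                vocab.createdAt, vocab.author, vocab.extractionMethod,
                vocab.importedFrom, vocab.modifiable, vocab.deletedAt,
                vocab.deletedBy,
            ])
            g.add((shape, SH.ignoredProperties, ignored))
    else:
        # statement (version) shape: versions are the resources that carry
        # a version number
        g.add((shape, SH.targetSubjectsOf, vocab.versionNumber))
        ps = _property_shape_iri(schema.schema_iri, subj.role_label)
        g.add((shape, SH.property, ps))
        g.add((ps, SH.path, vocab.subject))
        g.add((ps, SH.name, Literal(subj.role_label)))
        g.add((ps, SH.minCount, Literal(1)))
        if subj.max_values is not None:
            g.add((ps, SH.maxCount, Literal(subj.max_values)))
        qvs = BNode()
        g.add((ps, SH.qualifiedValueShape, qvs))
        g.add((qvs, SH["class"], vocab.SubjectPosition))
        g.add((ps, SH.qualifiedMinCount, Literal(1)))
        position_shapes[subj.role_label] = str(ps)
        # subject value class through the position instance
        vs = URIRef(str(ps) + "/value")
        g.add((shape, SH.property, vs))
        g.add((vs, SH.path, _seq_path(g, vocab.subject, RDF.value)))
        g.add((vs, SH.minCount, Literal(1)))
        _add_value_constraints(g, vs, subj.constraint)
        for p in schema.object_positions:
            pos_class = URIRef(schema.position_class_iri(p.role_label))
            link = vocab.position_property(p.required, literal=False)
            ps = _property_shape_iri(schema.schema_iri, p.role_label)
            g.add((shape, SH.property, ps))
            g.add((ps, SH.path, link))
            g.add((ps, SH.name, Literal(p.role_label)))
            qvs = BNode()
            g.add((ps, SH.qualifiedValueShape, qvs))
            g.add((qvs, SH["class"], pos_class))
            g.add((ps, SH.qualifiedMinCount, Literal(1 if p.required else 0)))
            if p.max_values is not None:
                g.add((ps, SH.qualifiedMaxCount, Literal(p.max_values)))
            position_shapes[p.role_label] = str(ps)
            # value constraints on the position-instance class
            nshape = URIRef(schema.position_class_iri(p.role_label) + "/shape")
            g.add((nshape, RDF.type, SH.NodeShape))
            g.add((nshape, SH.targetClass, pos_class))
            vps = URIRef(str(nshape) + "/value")
            g.add((nshape, SH.property, vps))
            g.add((vps, SH.path, RDF.value))
            g.add((vps, SH.minCount, Literal(1)))
            g.add((vps, SH.maxCount, Literal(1)))
            _add_value_constraints(g, vps, p.constraint)
    return ShapeBundle(graph=g, shape_iri=schema.schema_iri,
                       target_class=schema.type_iri, dialect=dialect,
                       position_shapes=position_shapes)


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Violation:
    focus: str
    path: str
    rule: str  # e.g. "minCount", "datatype", "class"
    message: str
    value: Optional[str] = None


@dataclass(frozen=True)
class ValidationReport:
    conforms: bool
    violations: Tuple[Violation, ...]

    def to_json_dict(self) -> dict:
        return {"conforms": self.conforms,
                "violations": [vars(v) for v in self.violations]}

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_json_dict(), **kwargs)

    def to_graph(self) -> Graph:
        g = Graph()
        g.bind("sh", SH)
        report = BNode()
        g.add((report, RDF.type, SH.ValidationReport))
        g.add((report, SH.conforms, Literal(self.conforms)))
        for v in self.violations:
            res = BNode()
            g.add((report, SH.result, res))
            g.add((res, RDF.type, SH.ValidationResult))
            g.add((res, SH.focusNode, URIRef(v.focus)))
            g.add((res, SH.resultPath, URIRef(v.path)))
            g.add((res, SH.resultMessage, Literal(v.message)))
            g.add((res, SH.resultSeverity, SH.Violation))
        return g

    def to_turtle(self) -> str:
        return self.to_graph().serialize(format="turtle")


def _subclass_closure(data: Graph, cls: URIRef) -> set:
    """``cls`` and every class the data graph asserts to be its (transitive)
    subclass."""
    out = {cls}
    frontier = [cls]
    while frontier:
        c = frontier.pop()
        for sub in data.subjects(RDFS.subClassOf, c):
            if sub not in out:
                out.add(sub)
                frontier.append(sub)
    return out


def _has_class(data: Graph, node, cls: URIRef) -> bool:
    if not isinstance(node, URIRef):
        return False
    admissible = _subclass_closure(data, cls)
    return any(t in admissible for t in data.objects(node, RDF.type))


def _path_values(data: Graph, focus, path, shapes: Graph) -> List:
    """Evaluate a SHACL path: either a predicate IRI or a sequence path
    given as an RDF list in the shapes graph."""
    if isinstance(path, URIRef):
        return list(data.objects(focus, path))
    steps = list(Collection(shapes, path))
    nodes = [focus]
    for step in steps:
        nodes = [o for n in nodes for o in data.objects(n, step)]
    return nodes


def _path_str(path, shapes: Graph) -> str:
    if isinstance(path, URIRef):
        return str(path)
    return "/".join(str(s) for s in Collection(shapes, path))


def _literal_in_range(value, lo, hi) -> Optional[bool]:
    try:
        v = float(value)
    except (ValueError, TypeError):
        return None
    if lo is not None and v < float(lo):
        return False
    if hi is not None and v > float(hi):
        return False
    return True


def validate_statement(data_graph: Graph, bundle: ShapeBundle) -> ValidationReport:
    """Validate a statement graph against a generated shape bundle.

    Returns a report that conforms iff there are no violations; each
    violation names the focus node and the offending position path.
    """
    shapes = bundle.graph
    violations: List[Violation] = []
    for shape in sorted(set(shapes.subjects(RDF.type, SH.NodeShape)), key=str):
        focuses = set()
        for cls in shapes.objects(shape, SH.targetClass):
            for c in _subclass_closure(data_graph, cls):
                focuses.update(data_graph.subjects(RDF.type, c))
        for pred in shapes.objects(shape, SH.targetSubjectsOf):
            focuses.update(data_graph.subjects(pred, None))
        if not focuses:
            continue
        pshapes = sorted(set(shapes.objects(shape, SH.property)), key=str)
        closed = shapes.value(shape, SH.closed)
        allowed = None
        if closed is not None and bool(closed):
            allowed = {RDF.type}
            ignored = shapes.value(shape, SH.ignoredProperties)
            if ignored is not None:
                allowed.update(Collection(shapes, ignored))
            for ps in pshapes:
                p = shapes.value(ps, SH.path)
                if isinstance(p, URIRef):
                    allowed.add(p)
        for focus in sorted(focuses, key=str):
            for ps in pshapes:
                violations.extend(
                    _check_property(data_graph, shapes, focus, ps))
            if allowed is not None:
                for pred in set(data_graph.predicates(focus, None)):
                    if pred not in allowed:
                        violations.append(Violation(
                            str(focus), str(pred), "closed",
                            f"predicate {pred} is not allowed by the closed "
                            "shape"))
    violations.sort(key=lambda v: (v.focus, v.path, v.rule, v.message))
    return ValidationReport(conforms=not violations,
                            violations=tuple(violations))


def _check_property(data: Graph, shapes: Graph, focus, pshape) -> List[Violation]:
    out: List[Violation] = []
    path = shapes.value(pshape, SH.path)
    if path is None:
        raise RosettaError(f"malformed shape: property shape {pshape} "
                           "has no sh:path")
    pstr = _path_str(path, shapes)
    values = _path_values(data, focus, path, shapes)

    def report(rule, message, value=None):
        out.append(Violation(str(focus), pstr, rule, message, value))

    mn = shapes.value(pshape, SH.minCount)
    if mn is not None and len(values) < int(mn):
        report("minCount",
               f"expected at least {int(mn)} value(s) on {pstr}, "
               f"found {len(values)}")
    mx = shapes.value(pshape, SH.maxCount)
    if mx is not None and len(values) > int(mx):
        report("maxCount",
               f"expected at most {int(mx)} value(s) on {pstr}, "
               f"found {len(values)}")

    cls = shapes.value(pshape, SH["class"])
    if cls is not None:
        for v in values:
            if not _has_class(data, v, cls):
                report("class",
                       f"value {v} is not an instance of {cls} or an "
                       "asserted subclass", str(v))
    dt = shapes.value(pshape, SH.datatype)
    if dt is not None:
        for v in values:
            if not isinstance(v, Literal) or (v.datatype or XSD.string) != dt:
                report("datatype", f"value {v} is not a literal of "
                                   f"datatype {dt}", str(v))
    pattern = shapes.value(pshape, SH.pattern)
    if pattern is not None:
        rx = re.compile(str(pattern))
        for v in values:
            if not isinstance(v, Literal) or not rx.search(str(v)):
                report("pattern",
                       f"value {v} does not match pattern {pattern}", str(v))
    lo = shapes.value(pshape, SH.minInclusive)
    hi = shapes.value(pshape, SH.maxInclusive)
    if lo is not None or hi is not None:
        for v in values:
            ok = _literal_in_range(v, lo, hi)
            if ok is False:
                report("range",
                       f"value {v} outside [{lo}, {hi}]", str(v))
            elif ok is None:
                report("range", f"value {v} is not numeric", str(v))

    qvs = shapes.value(pshape, SH.qualifiedValueShape)
    if qvs is not None:
        qcls = shapes.value(qvs, SH["class"])
        matching = [v for v in values
                    if qcls is None or _has_class(data, v, qcls)]
        qmn = shapes.value(pshape, SH.qualifiedMinCount)
        if qmn is not None and len(matching) < int(qmn):
            report("qualifiedMinCount",
                   f"expected at least {int(qmn)} value(s) of class {qcls} "
                   f"on {pstr}, found {len(matching)}")
        qmx = shapes.value(pshape, SH.qualifiedMaxCount)
        if qmx is not None and len(matching) > int(qmx):
            report("qualifiedMaxCount",
                   f"expected at most {int(qmx)} value(s) of class {qcls} "
                   f"on {pstr}, found {len(matching)}")
    return out
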