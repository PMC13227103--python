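"""Full-dialect model: anchors, versions, position instances.

The full dialect supports collaborative editing.  A version-independent
*anchor* resource identifies the statement; it points to its statement-type
data schema, optionally to a context (e.g. the publication the statement was
taken from), and — via ``has version`` — to an append-only sequence of
*version* resources with consecutive version numbers.  The anchor always
resolves to the newest non-deleted version.

Within a version, subjects and objects are not linked directly: each bound
value gets its own *position instance*, an instance of the shared
subject-position class or of the statement type's per-role object-position
class, carrying the value (``rdf:value``), its order rank (``order``) and
any boolean logical-property annotations.  This gives every subject and
object of every version its own IRI, enabling per-position edit history and
per-value citation.

Soft delete (of the anchor or of single versions) only ever *adds*
``deleted at`` / ``deleted by`` triples; content is never removed, so
provenance metadata stays accessible even when the data are withdrawn.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

from rdflib import Dataset, Graph, Literal, RDF, RDFS, URIRef
from rdflib.namespace import XSD

from .errors import (
    AllVersionsDeletedError,
    AlreadyDeletedError,
    AnchorDeletedError,
    GraphParseError,
    NotModifiableError,
    RosettaError,
    UnknownRoleError,
)
from .light import _add_resource_annotations, _binding_node, canonical_turtle
from .model import (
    IriMinter,
    ProvenanceMetadata,
    SchemaRegistry,
    StatementRecord,
    StatementTypeSchema,
    ValueBinding,
    check_record,
    slugify,
)
from .vocab import DEFAULT_VOCAB, RosettaVocabulary


@dataclass
class VersionRecord:
    """One immutable version of a statement.  The wrapped record's
    ``statement_iri`` is the version IRI; its provenance carries the
    editor (creator/author) and timestamp of this version."""

    version_iri: str
    version_number: int
    record: StatementRecord
    external_id: Optional[str] = None  # citable identifier, e.g. a DOI
    deleted_at: Optional[str] = None
    deleted_by: Optional[str] = None
    #: (role_label, property_name) -> bool logical annotations on the
    #: position instances of that role.
    annotations: Dict[Tuple[str, str], bool] = field(default_factory=dict)

    @property
    def is_deleted(self) -> bool:
        return self.deleted_at is not None


@dataclass
class AnchorRecord:
    """Version-independent identity of a statement plus its edit history."""

    anchor_iri: str
    type_iri: str
    schema_iri: str
    metadata: ProvenanceMetadata
    context_iri: Optional[str] = None
    versions: List[VersionRecord] = field(default_factory=list)

    @property
    def is_deleted(self) -> bool:
        return self.metadata.is_deleted

    def version(self, number: int) -> VersionRecord:
        for v in self.versions:
            if v.version_number == number:
                return v
        raise RosettaError(f"anchor {self.anchor_iri} has no version {number}")


@dataclass(frozen=True)
class HistoryEntry:
    version_number: int
    values: Tuple[ValueBinding, ...]
    editor: Optional[str]
    created_at: Optional[str]
    changed: bool


@dataclass(frozen=True)
class ContributorSummary:
    contributors: frozenset
    last_updated: Optional[str]


def _version_iri(anchor_iri: str, number: int) -> str:
    return f"{anchor_iri}/v{number}"


def _version_provenance(m: ProvenanceMetadata) -> ProvenanceMetadata:
    """Metadata ownership is split: creator/editor, timestamp and author
    live on versions; import source, modifiability and anchor-level deletion
    live on the anchor only."""
    return ProvenanceMetadata(creator=m.creator, created_at=m.created_at,
                              author=m.author)


def create_anchor(
    record: StatementRecord,
    schema: StatementTypeSchema,
    context_iri: Optional[str] = None,
    *,
    minter: Optional[IriMinter] = None,
) -> AnchorRecord:
    """Create an anchor whose version 1 holds ``record``'s content.

    The anchor takes over the record's provenance (creator, import source,
    modifiability); the version carries editor, timestamp and certainty.
    """
    check_record(schema, record)
    minter = minter or IriMinter()
    anchor_iri = minter.mint("anchor")
    v1 = VersionRecord(
        version_iri=_version_iri(anchor_iri, 1),
        version_number=1,
        record=replace(record, statement_iri=_version_iri(anchor_iri, 1),
                       context_iri=None,
                       provenance=_version_provenance(record.provenance)),
    )
    return AnchorRecord(
        anchor_iri=anchor_iri,
        type_iri=schema.type_iri,
        schema_iri=schema.schema_iri,
        metadata=record.provenance,
        context_iri=context_iri if context_iri is not None else record.context_iri,
        versions=[v1],
    )


def update_statement(
    anchor: AnchorRecord,
    schema: StatementTypeSchema,
    new_bindings: Mapping[str, Union[ValueBinding, Sequence[ValueBinding]]] = None,
    metadata: Optional[ProvenanceMetadata] = None,
    *,
    subject_bindings: Optional[Sequence[ValueBinding]] = None,
    negated: Optional[bool] = None,
    certainty: Optional[float] = None,
    external_id: Optional[str] = None,
) -> AnchorRecord:
    """Append a new version: the current version's content with the given
    positions rebound.  Earlier versions are never touched.  Fails on
    deleted or non-modifiable anchors and on constraint violations (in which
    case the version list is unchanged)."""
    if anchor.is_deleted:
        raise AnchorDeletedError(
            f"anchor {anchor.anchor_iri} is deleted; statements cannot be "
            "updated after deletion")
    if not anchor.metadata.modifiable:
        raise NotModifiableError(
            f"anchor {anchor.anchor_iri} is marked non-modifiable")
    current = resolve_current(anchor)
    number = max(v.version_number for v in anchor.versions) + 1
    viri = _version_iri(anchor.anchor_iri, number)

    bindings = dict(current.record.bindings)
    for role, val in (new_bindings or {}).items():
        pos = schema.position(role)  # raises UnknownRoleError
        vals = (val,) if isinstance(val, ValueBinding) else tuple(val)
        vals = tuple(replace(b, order_rank=i)
                     for i, b in enumerate(vals, start=1))
        if pos.constraint.kind == "resource":
            vals = tuple(
                replace(b, resource_class=pos.constraint.value_class)
                if b.is_resource and b.resource_class is None else b
                for b in vals)
        if vals:
            bindings[role] = vals
        else:
            bindings.pop(role, None)
    new_record = StatementRecord(
        statement_iri=viri,
        type_iri=current.record.type_iri,
        subject_bindings=tuple(
            replace(b, order_rank=i)
            for i, b in enumerate(subject_bindings, start=1))
        if subject_bindings is not None else current.record.subject_bindings,
        bindings=bindings,
        negated=current.record.negated if negated is None else negated,
        certainty=current.record.certainty if certainty is None else certainty,
        context_iri=None,
        provenance=_version_provenance(metadata or ProvenanceMetadata()),
    )
    check_record(schema, new_record)  # raises before any mutation
    anchor.versions.append(VersionRecord(
        version_iri=viri, version_number=number, record=new_record,
        external_id=external_id,
        annotations=dict(current.annotations)))
    return anchor


def resolve_current(anchor: AnchorRecord) -> VersionRecord:
    """The version with the highest version number among non-deleted
    versions.  Distinguishes a deleted anchor from an anchor whose versions
    are all individually deleted."""
    if anchor.is_deleted:
        raise AnchorDeletedError(f"anchor {anchor.anchor_iri} is deleted")
    live = [v for v in anchor.versions if not v.is_deleted]
    if not live:
        raise AllVersionsDeletedError(
            f"all versions of anchor {anchor.anchor_iri} are deleted")
    return max(live, key=lambda v: v.version_number)


def soft_delete(target: Union[AnchorRecord, VersionRecord],
                who: str, when: str) -> Union[AnchorRecord, VersionRecord]:
    """Mark an anchor or a single version deleted.  Content is retained;
    only the deletion metadata is added."""
    if isinstance(target, AnchorRecord):
        if target.is_deleted:
            raise AlreadyDeletedError(
                f"anchor {target.anchor_iri} is already deleted")
        target.metadata = replace(target.metadata,
                                  deleted_at=when, deleted_by=who)
        return target
    if target.is_deleted:
        raise AlreadyDeletedError(
            f"version {target.version_iri} is already deleted")
    target.deleted_at = when
    target.deleted_by = who
    return target


def retrieve(anchor: AnchorRecord) -> dict:
    """FAIR retrieval view: metadata is always returned; bindings are
    suppressed once the anchor is deleted (metadata stays accessible even
    when the data are no longer available)."""
    out = {
        "anchor_iri": anchor.anchor_iri,
        "type_iri": anchor.type_iri,
        "deleted": anchor.is_deleted,
        "metadata": anchor.metadata,
        "content": None,
    }
    if not anchor.is_deleted:
        try:
            out["content"] = resolve_current(anchor)
        except AllVersionsDeletedError:
            out["all_versions_deleted"] = True
    return out


def position_history(
    anchor: AnchorRecord, schema: StatementTypeSchema, role_label: str
) -> List[HistoryEntry]:
    """Per-position edit history: one entry per version in version order;
    an entry is flagged as a change when its value list differs from the
    previous version's."""
    schema.position(role_label)  # raises UnknownRoleError
    is_subject = role_label == schema.subject_position.role_label
    entries: List[HistoryEntry] = []
    prev: Optional[Tuple[ValueBinding, ...]] = None
    for v in sorted(anchor.versions, key=lambda v: v.version_number):
        vals = (v.record.subject_bindings if is_subject
                else v.record.values(role_label))
        entries.append(HistoryEntry(
            version_number=v.version_number,
            values=vals,
            editor=v.record.provenance.creator or v.record.provenance.author,
            created_at=v.record.provenance.created_at,
            changed=(prev is not None and vals != prev),
        ))
        prev = vals
    return entries


def contributors(anchor: AnchorRecord) -> ContributorSummary:
    """Distinct creators/authors across all versions; the last-update
    timestamp is the creation date of the highest version."""
    if not anchor.versions:
        raise RosettaError(f"anchor {anchor.anchor_iri} has no versions")
    people = set()
    for v in anchor.versions:
        for name in (v.record.provenance.creator, v.record.provenance.author):
            if name:
                people.add(name)
    latest = max(anchor.versions, key=lambda v: v.version_number)
    return ContributorSummary(contributors=frozenset(people),
                              last_updated=latest.record.provenance.created_at)


def annotate_logical_property(
    version: VersionRecord,
    schema: StatementTypeSchema,
    role_label: str,
    property_name: str,
    flag: bool,
) -> VersionRecord:
    """Attach a boolean logical-property annotation (e.g. ``transitive``)
    to the position instances of one role.  The property-name set is open;
    it must be a valid vocabulary local name."""
    schema.position(role_label)  # raises UnknownRoleError
    DEFAULT_VOCAB.logical_property(property_name)  # name validity
    version.annotations[(role_label, property_name)] = flag
    return version


# ---------------------------------------------------------------------------
# RDF serialisation
# ---------------------------------------------------------------------------

def _subject_instance_iri(version_iri: str, rank: int) -> str:
    return f"{version_iri}/subject/{rank}"


def _object_instance_iri(version_iri: str, role: str, rank: int) -> str:
    return f"{version_iri}/{slugify(role)}/{rank}"


def _anchor_triples(anchor: AnchorRecord, vocab: RosettaVocabulary) -> Graph:
    g = Graph()
    a = URIRef(anchor.anchor_iri)
    g.add((a, RDF.type, URIRef(anchor.type_iri)))
    g.add((a, vocab.hasDataSchema, URIRef(anchor.schema_iri)))
    if anchor.context_iri is not None:
        g.add((a, vocab.hasContext, URIRef(anchor.context_iri)))
    m = anchor.metadata
    for pred, val in ((vocab.creator, m.creator), (vocab.author, m.author),
                      (vocab.extractionMethod, m.extraction_method),
                      (vocab.importedFrom, m.imported_from),
                      (vocab.deletedBy, m.deleted_by)):
        if val is not None:
            g.add((a, pred, Literal(val)))
    if m.created_at is not None:
        g.add((a, vocab.createdAt, Literal(m.created_at, datatype=XSD.dateTime)))
    if m.deleted_at is not None:
        g.add((a, vocab.deletedAt, Literal(m.deleted_at, datatype=XSD.dateTime)))
    g.add((a, vocab.modifiable,
           Literal("true" if m.modifiable else "false", datatype=XSD.boolean)))
    for v in anchor.versions:
        g.add((a, vocab.hasVersion, URIRef(v.version_iri)))
    return g


def _version_triples(
    version: VersionRecord,
    anchor: AnchorRecord,
    schema: StatementTypeSchema,
    vocab: RosettaVocabulary,
    simplified_links: bool = False,
) -> Graph:
    g = Graph()
    v = URIRef(version.version_iri)
    rec = version.record
    g.add((v, RDF.type, URIRef(anchor.type_iri)))
    if rec.negated:
        g.add((v, RDF.type, vocab.Negation))
    g.add((v, vocab.versionNumber,
           Literal(str(version.version_number), datatype=XSD.integer)))
    if version.external_id is not None:
        g.add((v, vocab.versionIdentifier, Literal(version.external_id)))
    m = rec.provenance
    for pred, val in ((vocab.creator, m.creator), (vocab.author, m.author)):
        if val is not None:
            g.add((v, pred, Literal(val)))
    if m.created_at is not None:
        g.add((v, vocab.createdAt, Literal(m.created_at, datatype=XSD.dateTime)))
    if rec.certainty is not None:
        g.add((v, vocab.certainty,
               Literal(str(rec.certainty), datatype=XSD.decimal)))
    if version.deleted_at is not None:
        g.add((v, vocab.deletedAt,
               Literal(version.deleted_at, datatype=XSD.dateTime)))
    if version.deleted_by is not None:
        g.add((v, vocab.deletedBy, Literal(version.deleted_by)))

    for b in rec.subject_bindings:
        inst = URIRef(_subject_instance_iri(version.version_iri, b.order_rank))
        g.add((v, vocab.subject, inst))
        g.add((inst, RDF.type, vocab.SubjectPosition))
        g.add((inst, RDF.value, _binding_node(b)))
        g.add((inst, vocab.order,
               Literal(str(b.order_rank), datatype=XSD.integer)))
        _add_resource_annotations(g, b)
        _add_position_annotations(
            g, inst, version, schema.subject_position.role_label, vocab)
    for p in schema.object_positions:
        if simplified_links:
            link = vocab.hasObjectPosition
        else:
            link = vocab.position_property(p.required, literal=False)
        pos_class = URIRef(schema.position_class_iri(p.role_label))
        for b in rec.values(p.role_label):
            inst = URIRef(_object_instance_iri(
                version.version_iri, p.role_label, b.order_rank))
            g.add((v, link, inst))
            g.add((inst, RDF.type, pos_class))
            g.add((inst, RDF.value, _binding_node(b)))
            g.add((inst, vocab.order,
                   Literal(str(b.order_rank), datatype=XSD.integer)))
            _add_resource_annotations(g, b)
            _add_position_annotations(g, inst, version, p.role_label, vocab)
    return g


def _add_position_annotations(g: Graph, inst: URIRef, version: VersionRecord,
                              role: str, vocab: RosettaVocabulary) -> None:
    for (r, name), flag in sorted(version.annotations.items()):
        if r == role:
            g.add((inst, vocab.logical_property(name),
                   Literal("true" if flag else "false", datatype=XSD.boolean)))


def to_full_graph(
    anchor: AnchorRecord,
    schema: StatementTypeSchema,
    vocab: RosettaVocabulary = DEFAULT_VOCAB,
    *,
    simplified_links: bool = False,
) -> Graph:
    """Flattened (single-graph) serialisation of an anchor with all its
    versions.  With ``simplified_links`` the argument/adjunct distinction is
    dropped and versions link to position instances through the single
    ``has object position`` property."""
    g = Graph()
    g.bind("rosetta", vocab.namespace)
    g.bind("xsd", XSD)
    g += _anchor_triples(anchor, vocab)
    for v in anchor.versions:
        g += _version_triples(v, anchor, schema, vocab, simplified_links)
    return g


def to_full_dataset(
    anchor: AnchorRecord,
    schema: StatementTypeSchema,
    vocab: RosettaVocabulary = DEFAULT_VOCAB,
) -> Dataset:
    """Named-graph serialisation (TriG/N-Quads): anchor triples in the
    default graph, each version in its own named graph whose IRI is the
    version IRI."""
    ds = Dataset()
    ds.bind("rosetta", vocab.namespace)
    ds.bind("xsd", XSD)
    for t in _anchor_triples(anchor, vocab):
        ds.default_graph.add(t)
    for v in anchor.versions:
        ctx = ds.graph(URIRef(v.version_iri))
        for t in _version_triples(v, anchor, schema, vocab):
            ctx.add(t)
    return ds


def canonical_full_text(anchor: AnchorRecord,
                        schema: StatementTypeSchema,
                        vocab: RosettaVocabulary = DEFAULT_VOCAB) -> str:
    """Deterministic flattened serialisation (sorted triples)."""
    return canonical_turtle(to_full_graph(anchor, schema, vocab))


# ---------------------------------------------------------------------------
# parsing
# ---------------------------------------------------------------------------

def _parse_literal_meta(graph: Graph, node: URIRef,
                        vocab: RosettaVocabulary) -> ProvenanceMetadata:
    def val(pred):
        o = graph.value(node, pred)
        return str(o) if o is not None else None

    modif = graph.value(node, vocab.modifiable)
    return ProvenanceMetadata(
        creator=val(vocab.creator),
        created_at=val(vocab.createdAt),
        author=val(vocab.author),
        extraction_method=val(vocab.extractionMethod),
        imported_from=val(vocab.importedFrom),
        modifiable=(str(modif) in ("true", "1")) if modif is not None else True,
        deleted_at=val(vocab.deletedAt),
        deleted_by=val(vocab.deletedBy),
    )


def _parse_position_instance(graph: Graph, inst: URIRef,
                             vocab: RosettaVocabulary):
    value = graph.value(inst, RDF.value)
    if value is None:
        raise GraphParseError(
            f"dangling position instance {inst}: no rdf:value")
    order = graph.value(inst, vocab.order)
    rank = int(order) if order is not None else 1
    if isinstance(value, URIRef):
        label = graph.value(value, RDFS.label)
        klass = None
        for t in sorted(graph.objects(value, RDF.type), key=str):
            klass = str(t)
            break
        b = ValueBinding.resource(str(value),
                                  str(label) if label is not None else None,
                                  resource_class=klass, order_rank=rank)
    else:
        b = ValueBinding.literal(str(value), str(value.datatype),
                                 order_rank=rank)
    annotations = {}
    for pred, obj in graph.predicate_objects(inst):
        if (str(pred).startswith(vocab.namespace)
                and pred not in (vocab.order,)
                and isinstance(obj, Literal) and obj.datatype == XSD.boolean):
            name = str(pred)[len(vocab.namespace):]
            annotations[name] = str(obj) in ("true", "1")
    return b, annotations


def from_full_graph(
    graph: Graph,
    registry: SchemaRegistry,
    anchor_iri: Optional[str] = None,
    vocab: RosettaVocabulary = DEFAULT_VOCAB,
) -> AnchorRecord:
    """Parse an anchor (with all versions, order, annotations, soft-delete
    markers) back out of a full-dialect graph.  Lossless inverse of
    :func:`to_full_graph` / :func:`to_full_dataset` over valid anchors."""
    anchors = []
    for s in sorted(set(graph.subjects(vocab.hasDataSchema, None)), key=str):
        if anchor_iri is None or str(s) == anchor_iri:
            anchors.append(s)
    if not anchors:
        raise GraphParseError("no anchor resource (with a data-schema link) "
                              "found in the graph")
    a = anchors[0]
    type_iri = None
    for t in graph.objects(a, RDF.type):
        if str(t) in registry:
            type_iri = str(t)
            break
    if type_iri is None:
        raise GraphParseError(
            f"anchor {a} is not typed into a registered statement class")
    schema = registry.get(type_iri)
    context = graph.value(a, vocab.hasContext)
    metadata = _parse_literal_meta(graph, a, vocab)

    versions: List[VersionRecord] = []
    for viri in graph.objects(a, vocab.hasVersion):
        number = graph.value(viri, vocab.versionNumber)
        if number is None:
            raise GraphParseError(f"version {viri} has no version number")
        negated = (viri, RDF.type, vocab.Negation) in graph
        certainty = graph.value(viri, vocab.certainty)
        ext = graph.value(viri, vocab.versionIdentifier)
        vmeta = _parse_literal_meta(graph, viri, vocab)

        subjects = []
        annotations: Dict[Tuple[str, str], bool] = {}
        for inst in graph.objects(viri, vocab.subject):
            b, anns = _parse_position_instance(graph, inst, vocab)
            subjects.append(b)
            for name, flag in anns.items():
                annotations[(schema.subject_position.role_label, name)] = flag
        bindings: Dict[str, List[ValueBinding]] = {}
        link_preds = {
            vocab.position_property(True, literal=False),
            vocab.position_property(False, literal=False),
            vocab.hasObjectPosition,
        }
        for link in link_preds:
            for inst in graph.objects(viri, link):
                pos_class = None
                for t in graph.objects(inst, RDF.type):
                    role = schema.role_for_position_class(str(t))
                    if role is not None:
                        pos_class = role
                        break
                if pos_class is None:
                    raise GraphParseError(
                        f"dangling position instance {inst}: not typed into "
                        "any object-position class of the schema")
                b, anns = _parse_position_instance(graph, inst, vocab)
                bindings.setdefault(pos_class, []).append(b)
                for name, flag in anns.items():
                    annotations[(pos_class, name)] = flag
        record = StatementRecord(
            statement_iri=str(viri),
            type_iri=type_iri,
            subject_bindings=tuple(
                sorted(subjects, key=lambda b: b.order_rank)),
            bindings={
                role: tuple(sorted(vals, key=lambda b: b.order_rank))
                for role, vals in bindings.items()},
            negated=negated,
            certainty=float(certainty) if certainty is not None else None,
            context_iri=None,
            provenance=replace(vmeta, deleted_at=None, deleted_by=None),
        )
        versions.append(VersionRecord(
            version_iri=str(viri),
            version_number=int(number),
            record=record,
            external_id=str(ext) if ext is not None else None,
            deleted_at=vmeta.deleted_at,
            deleted_by=vmeta.deleted_by,
            annotations=annotations,
        ))
    versions.sort(key=lambda v: v.version_number)
    numbers = [v.version_number for v in versions]
    if numbers != list(range(1, len(versions) + 1)):
        raise GraphParseError(
            f"version numbers {numbers} are not consecutive from 1")
    return AnchorRecord(
        anchor_iri=str(a),
        type_iri=type_iri,
        schema_iri=str(graph.value(a, vocab.hasDataSchema)),
        metadata=metadata,
        context_iri=str(context) if context is not None else None,
        versions=versions,
    )


def from_full_dataset(
    ds: Dataset,
    registry: SchemaRegistry,
    anchor_iri: Optional[str] = None,
    vocab: RosettaVocabulary = DEFAULT_VOCAB,
) -> AnchorRecord:
    """Parse an anchor from a named-graph dataset by flattening it."""
    g = Graph()
    for quad in ds.quads((None, None, None, None)):
        g.add(quad[:3])
    return from_full_graph(g, registry, anchor_iri, vocab)
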