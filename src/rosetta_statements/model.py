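"""Statement types and token statements.

A *statement type* is defined by a verb/predicate and a set of syntactic
positions: one subject position and zero or more ordered object positions.
Each position carries a thematic role label (e.g. ``QUALITY``, ``UNIT``),
display texts for the derived sentence template, an argument/adjunct flag
(required vs optional), a cardinality bound, and a constraint — an ontology
class for resource positions, an XSD datatype (optionally with a regex
pattern and a numeric range) for literal positions.

A *statement record* is one token statement of a type: bindings of positions
to resource references or typed literals, plus a negation flag, an optional
certainty in [0, 1], an optional context link, and provenance metadata.
"""

from __future__ import annotations

import random
import re
import uuid
from dataclasses import dataclass, field, replace
from datetime import date, datetime
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple, Union

from .errors import (
    BindingError,
    CardinalityError,
    DatatypeLexicalError,
    DuplicateRoleError,
    MissingRequiredPositionError,
    SchemaError,
    UnknownDatatypeError,
    UnknownRoleError,
)

XSD_NS = "http://www.w3.org/2001/XMLSchema#"

#: Statement-type editor datatype names -> XSD datatype IRIs.
EDITOR_DATATYPES: Dict[str, str] = {
    "text": XSD_NS + "string",
    "URL": XSD_NS + "anyURI",
    "date": XSD_NS + "date",
    "datetime": XSD_NS + "dateTime",
    "boolean": XSD_NS + "boolean",
    "integer": XSD_NS + "integer",
    "decimal": XSD_NS + "decimal",
    "float": XSD_NS + "float",
}

_XSD_TO_EDITOR = {v: k for k, v in EDITOR_DATATYPES.items()}

DEFAULT_TYPE_BASE = "https://w3id.org/rosetta-statement/type/"
DEFAULT_INSTANCE_BASE = "https://example.org/kg/"


def xsd_datatype_for(editor_type: str) -> str:
    """Map a statement-type editor datatype name to its XSD datatype IRI.

    The supported names are ``text``, ``URL``, ``date``, ``datetime``,
    ``boolean``, ``integer``, ``decimal`` and ``float`` (case-insensitive).
    """
    key = editor_type if editor_type in EDITOR_DATATYPES else editor_type.lower()
    if key == "url":
        key = "URL"
    try:
        return EDITOR_DATATYPES[key]
    except KeyError:
        raise UnknownDatatypeError(
            f"unknown editor datatype {editor_type!r}; expected one of "
            f"{sorted(EDITOR_DATATYPES)}"
        ) from None


def editor_type_for_xsd(datatype_iri: str) -> Optional[str]:
    """Inverse of :func:`xsd_datatype_for`; ``None`` for foreign datatypes."""
    return _XSD_TO_EDITOR.get(datatype_iri)


def slugify(label: str) -> str:
    """Lowercase-hyphen slug used when minting type IRIs from labels."""
    slug = re.sub(r"[^a-z0-9]+", "-", label.lower()).strip("-")
    if not slug:
        raise SchemaError(f"label {label!r} yields an empty IRI slug")
    return slug


class IriMinter:
    """Mints instance IRIs: UUIDv4-based, injective within a run and
    reproducible under a fixed seed.  No blank nodes are ever used, so node
    identity is stable across serialisations, diffs and version comparisons.
    """

    def __init__(self, base: str = DEFAULT_INSTANCE_BASE, seed: Optional[int] = None):
        self.base = base
        self._rng = random.Random(seed)
        self._seen: set = set()

    def mint(self, kind: str = "statement") -> str:
        while True:
            u = uuid.UUID(int=self._rng.getrandbits(128), version=4)
            iri = f"{self.base}{kind}/{u}"
            if iri not in self._seen:
                self._seen.add(iri)
                return iri


# ---------------------------------------------------------------------------
# schema types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConstraintSpec:
    """Constraint of one position.

    ``kind`` is ``"resource"`` (value must be an instance of ``value_class``
    or one of its subclasses) or ``"literal"`` (value must be a lexical form
    valid for ``datatype``, one of the editor datatype names).  Constraint
    classes are opaque IRIs: no term lookup is performed.
    """

    kind: str
    value_class: Optional[str] = None
    datatype: Optional[str] = None
    pattern: Optional[str] = None
    minimum: Optional[float] = None
    maximum: Optional[float] = None

    @property
    def datatype_iri(self) -> Optional[str]:
        return xsd_datatype_for(self.datatype) if self.datatype else None

    @classmethod
    def resource(cls, value_class: str) -> "ConstraintSpec":
        return cls(kind="resource", value_class=value_class)

    @classmethod
    def literal(
        cls,
        datatype: str,
        pattern: Optional[str] = None,
        minimum: Optional[float] = None,
        maximum: Optional[float] = None,
    ) -> "ConstraintSpec":
        return cls(kind="literal", datatype=datatype, pattern=pattern,
                   minimum=minimum, maximum=maximum)


@dataclass(frozen=True)
class PositionSpec:
    """One syntactic position (slot) of a statement type."""

    role_label: str
    constraint: ConstraintSpec
    required: bool = True
    placeholder_text: str = ""
    preposition_text: str = ""
    postposition_text: str = ""
    description: str = ""
    max_values: Optional[int] = 1  # None = unbounded
    index: int = 0  # 1-based template order; 0 for the subject position


@dataclass(frozen=True)
class StatementTypeSchema:
    """A statement type: verb label, subject position, ordered object
    positions, and the IRI of its derived data schema (shape)."""

    type_iri: str
    label: str
    subject_position: PositionSpec
    object_positions: Tuple[PositionSpec, ...]
    schema_iri: str
    description: str = ""
    example_sentences: Tuple[str, ...] = ()
    #: How the verb is displayed inside the dynamic label (defaults to
    #: ``label``); e.g. type ``has measurement`` displays as ``has``.
    verb_display: Optional[str] = None

    @property
    def verb(self) -> str:
        return self.verb_display if self.verb_display is not None else self.label

    @property
    def roles(self) -> Tuple[str, ...]:
        return tuple(p.role_label for p in self.object_positions)

    def position(self, role_label: str) -> PositionSpec:
        if role_label == self.subject_position.role_label:
            return self.subject_position
        for p in self.object_positions:
            if p.role_label == role_label:
                return p
        raise UnknownRoleError(role_label)

    def position_by_index(self, index: int) -> PositionSpec:
        for p in self.object_positions:
            if p.index == index:
                return p
        raise UnknownRoleError(f"index {index}")

    def position_class_iri(self, role_label: str) -> str:
        """Object-position class IRI (full dialect), minted once per
        statement type."""
        self.position(role_label)  # raises UnknownRoleError
        return f"{self.type_iri}/position/{slugify(role_label)}"

    def role_for_position_class(self, class_iri: str) -> Optional[str]:
        for p in self.object_positions:
            if self.position_class_iri(p.role_label) == class_iri:
                return p.role_label
        return None

    @property
    def literal_positions(self) -> Tuple[PositionSpec, ...]:
        return tuple(p for p in self.object_positions
                     if p.constraint.kind == "literal")


@dataclass(frozen=True)
class SchemaIssue:
    """One violated schema invariant; issues are data, not exceptions."""

    field: str
    rule: str
    message: str


# ---------------------------------------------------------------------------
# token statement types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ValueBinding:
    """One value bound into a position: either a resource reference (IRI +
    human label, optionally with the instance's own class) or a typed
    literal.  ``display_text`` is presentation-only (e.g. ``4th of July
    2021`` alongside ``2021-07-04``) and excluded from equality because it is
    not part of the statement's semantic content.
    """

    resource_iri: Optional[str] = None
    resource_label: Optional[str] = None
    resource_class: Optional[str] = None
    lexical: Optional[str] = None
    datatype: Optional[str] = None  # XSD datatype IRI
    order_rank: int = 1
    display_text: Optional[str] = field(default=None, compare=False)

    @property
    def is_resource(self) -> bool:
        return self.resource_iri is not None

    @classmethod
    def resource(cls, iri: str, label: Optional[str] = None,
                 resource_class: Optional[str] = None,
                 display_text: Optional[str] = None,
                 order_rank: int = 1) -> "ValueBinding":
        return cls(resource_iri=iri, resource_label=label,
                   resource_class=resource_class, display_text=display_text,
                   order_rank=order_rank)

    @classmethod
    def literal(cls, lexical: str, datatype: str,
                display_text: Optional[str] = None,
                order_rank: int = 1) -> "ValueBinding":
        if datatype in EDITOR_DATATYPES:
            datatype = EDITOR_DATATYPES[datatype]
        return cls(lexical=lexical, datatype=datatype,
                   display_text=display_text, order_rank=order_rank)

    def display_value(self) -> str:
        if self.display_text is not None:
            return self.display_text
        if self.is_resource:
            return self.resource_label or self.resource_iri
        return self.lexical


@dataclass(frozen=True)
class ProvenanceMetadata:
    """Who created/authored a statement, how it got into the graph, and
    whether/when it was soft-deleted.  Timestamps are ISO-8601 strings."""

    creator: Optional[str] = None
    created_at: Optional[str] = None
    author: Optional[str] = None
    extraction_method: Optional[str] = None
    imported_from: Optional[str] = None
    modifiable: bool = True
    deleted_at: Optional[str] = None
    deleted_by: Optional[str] = None

    def __post_init__(self):
        if (self.deleted_at is None) != (self.deleted_by is None):
            raise BindingError(
                "deleted_at and deleted_by must both be present or both absent"
            )

    @property
    def is_deleted(self) -> bool:
        return self.deleted_at is not None


@dataclass(frozen=True)
class StatementRecord:
    """One token statement, valid against its type's schema."""

    statement_iri: str
    type_iri: str
    subject_bindings: Tuple[ValueBinding, ...]
    bindings: Mapping[str, Tuple[ValueBinding, ...]]
    negated: bool = False
    certainty: Optional[float] = None
    context_iri: Optional[str] = None
    provenance: ProvenanceMetadata = field(default_factory=ProvenanceMetadata)

    def values(self, role_label: str) -> Tuple[ValueBinding, ...]:
        return tuple(self.bindings.get(role_label, ()))

    def __eq__(self, other):
        if not isinstance(other, StatementRecord):
            return NotImplemented
        return (
            self.statement_iri == other.statement_iri
            and self.type_iri == other.type_iri
            and self.subject_bindings == other.subject_bindings
            and dict(self.bindings) == dict(other.bindings)
            and self.negated == other.negated
            and self.certainty == other.certainty
            and self.context_iri == other.context_iri
            and self.provenance == other.provenance
        )

    __hash__ = None


# ---------------------------------------------------------------------------
# lexical validation
# ---------------------------------------------------------------------------

_DECIMAL_RE = re.compile(r"^[+-]?(\d+(\.\d*)?|\.\d+)$")
_INTEGER_RE = re.compile(r"^[+-]?\d+$")


def lexical_is_valid(lexical: str, datatype_iri: str) -> bool:
    """Check a lexical form against its XSD datatype (for the editor
    datatypes; foreign datatypes are accepted as-is)."""
    editor = editor_type_for_xsd(datatype_iri)
    if editor is None or editor == "text":
        return True
    if editor == "integer":
        return bool(_INTEGER_RE.match(lexical))
    if editor == "decimal":
        return bool(_DECIMAL_RE.match(lexical))
    if editor == "float":
        try:
            float(lexical)
            return True
        except ValueError:
            return lexical in ("INF", "-INF", "NaN")
    if editor == "boolean":
        return lexical in ("true", "false", "0", "1")
    if editor == "date":
        try:
            date.fromisoformat(lexical[:10])
            return len(lexical) >= 10
        except ValueError:
            return False
    if editor == "datetime":
        try:
            datetime.fromisoformat(lexical)
            return True
        except ValueError:
            return False
    if editor == "URL":
        return ":" in lexical and " " not in lexical
    return True


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def define_statement_type(
    label: str,
    description: str = "",
    examples: Sequence[str] = (),
    subject_spec: PositionSpec = None,
    object_specs: Sequence[PositionSpec] = (),
    *,
    verb_display: Optional[str] = None,
    base_iri: str = DEFAULT_TYPE_BASE,
) -> StatementTypeSchema:
    """Define a new statement type from a verb label and position specs.

    Object positions are re-indexed contiguously 1..n in the given order;
    the type IRI is slugged from the label and the schema (shape) IRI is
    derived from it.  Raises on duplicate role labels or a subject position
    with a literal constraint.
    """
    if not label or not label.strip():
        raise SchemaError("statement-type label must be non-empty")
    if subject_spec is None:
        raise SchemaError("a subject position spec is required")
    if subject_spec.constraint.kind != "resource":
        raise SchemaError(
            f"subject position {subject_spec.role_label!r} must have a "
            f"resource constraint, got {subject_spec.constraint.kind!r}"
        )
    seen = {subject_spec.role_label}
    for spec in object_specs:
        if spec.role_label in seen:
            raise DuplicateRoleError(spec.role_label)
        seen.add(spec.role_label)
    type_iri = base_iri + slugify(label)
    objects = tuple(
        replace(spec, index=i) for i, spec in enumerate(object_specs, start=1)
    )
    return StatementTypeSchema(
        type_iri=type_iri,
        label=label.strip(),
        description=description,
        example_sentences=tuple(examples),
        subject_position=replace(subject_spec, index=0),
        object_positions=objects,
        schema_iri=type_iri + "/schema",
        verb_display=verb_display,
    )


def validate_type_schema(schema: StatementTypeSchema) -> List[SchemaIssue]:
    """Check every schema invariant; the empty list means the schema is
    well-formed.  Each issue names the offending field and the violated
    rule."""
    issues: List[SchemaIssue] = []
    if not schema.label or not schema.label.strip():
        issues.append(SchemaIssue("label", "non-empty-label",
                                  "statement-type label is empty"))
    if schema.subject_position.constraint.kind != "resource":
        issues.append(SchemaIssue(
            "subject_position", "subject-resource-kind",
            f"subject position {schema.subject_position.role_label!r} has a "
            f"{schema.subject_position.constraint.kind!r} constraint; "
            "subjects must be resources"))
    seen = {schema.subject_position.role_label}
    for p in schema.object_positions:
        if p.role_label in seen:
            issues.append(SchemaIssue(
                "object_positions", "unique-role-labels",
                f"role label {p.role_label!r} appears more than once"))
        seen.add(p.role_label)
    indices = sorted(p.index for p in schema.object_positions)
    if indices != list(range(1, len(schema.object_positions) + 1)):
        issues.append(SchemaIssue(
            "object_positions", "contiguous-indices",
            f"position indices {indices} are not a contiguous 1..n sequence"))
    for p in (schema.subject_position, *schema.object_positions):
        c = p.constraint
        where = f"position {p.role_label!r}"
        if c.kind not in ("resource", "literal"):
            issues.append(SchemaIssue(
                "constraint", "known-kind",
                f"{where}: unknown constraint kind {c.kind!r}"))
            continue
        if c.kind == "resource":
            if not c.value_class:
                issues.append(SchemaIssue(
                    "constraint", "resource-needs-class",
                    f"{where}: resource constraint without a value class"))
            if c.datatype:
                issues.append(SchemaIssue(
                    "constraint", "exactly-one-of-class-datatype",
                    f"{where}: resource constraint must not carry a datatype"))
        else:
            if not c.datatype:
                issues.append(SchemaIssue(
                    "constraint", "literal-needs-datatype",
                    f"{where}: literal constraint without a datatype"))
            else:
                try:
                    xsd_datatype_for(c.datatype)
                except UnknownDatatypeError:
                    issues.append(SchemaIssue(
                        "constraint", "known-datatype",
                        f"{where}: unknown datatype {c.datatype!r}"))
            if c.value_class:
                issues.append(SchemaIssue(
                    "constraint", "exactly-one-of-class-datatype",
                    f"{where}: literal constraint must not carry a value class"))
            if c.pattern is not None:
                try:
                    re.compile(c.pattern)
                except re.error as exc:
                    issues.append(SchemaIssue(
                        "constraint", "valid-pattern",
                        f"{where}: invalid regex pattern: {exc}"))
            if (c.minimum is not None and c.maximum is not None
                    and c.minimum > c.maximum):
                issues.append(SchemaIssue(
                    "constraint", "min-le-max",
                    f"{where}: minimum {c.minimum} exceeds maximum {c.maximum}"))
        if p.max_values is not None and p.max_values < 1:
            issues.append(SchemaIssue(
                "max_values", "positive-max-values",
                f"{where}: max_values must be positive or unbounded"))
    return issues


def reorder_positions(
    schema: StatementTypeSchema, order: Sequence[str]
) -> StatementTypeSchema:
    """Reassign object-position indices 1..n to follow ``order`` (a
    permutation of the existing role labels); everything else unchanged."""
    existing = set(schema.roles)
    given = list(order)
    if sorted(given) != sorted(existing) or len(given) != len(existing):
        missing = existing - set(given)
        unknown = set(given) - existing
        parts = []
        if missing:
            parts.append(f"missing {sorted(missing)}")
        if unknown:
            parts.append(f"unknown {sorted(unknown)}")
        raise SchemaError(
            "reorder must be a permutation of the object role labels: "
            + "; ".join(parts or ["duplicates present"]))
    by_role = {p.role_label: p for p in schema.object_positions}
    reordered = tuple(
        replace(by_role[r], index=i) for i, r in enumerate(given, start=1)
    )
    return replace(schema, object_positions=reordered)


def _check_binding(position: PositionSpec, b: ValueBinding) -> None:
    c = position.constraint
    if c.kind == "resource":
        if not b.is_resource:
            raise BindingError(
                f"position {position.role_label!r} requires a resource, got "
                f"literal {b.lexical!r}")
    else:
        if b.is_resource:
            raise BindingError(
                f"position {position.role_label!r} requires a "
                f"{c.datatype} literal, got resource {b.resource_iri}")
        expected = c.datatype_iri
        if b.datatype != expected:
            raise DatatypeLexicalError(
                position.role_label, b.lexical or "",
                f"{c.datatype} (datatype IRI mismatch: {b.datatype})")
        if not lexical_is_valid(b.lexical or "", expected):
            raise DatatypeLexicalError(position.role_label, b.lexical or "",
                                       c.datatype)
        if c.pattern is not None and not re.search(c.pattern, b.lexical or ""):
            raise BindingError(
                f"value {b.lexical!r} in position {position.role_label!r} "
                f"does not match pattern {c.pattern!r}")
        if c.minimum is not None or c.maximum is not None:
            try:
                num = float(b.lexical)
            except (TypeError, ValueError):
                raise DatatypeLexicalError(position.role_label,
                                           b.lexical or "", c.datatype)
            if c.minimum is not None and num < c.minimum:
                raise BindingError(
                    f"value {b.lexical!r} in position {position.role_label!r} "
                    f"is below the minimum {c.minimum}")
            if c.maximum is not None and num > c.maximum:
                raise BindingError(
                    f"value {b.lexical!r} in position {position.role_label!r} "
                    f"exceeds the maximum {c.maximum}")


def _rank(bindings: Iterable[ValueBinding]) -> Tuple[ValueBinding, ...]:
    """Contiguous order ranks 1..k in the given order."""
    return tuple(replace(b, order_rank=i)
                 for i, b in enumerate(bindings, start=1))


def check_record(schema: StatementTypeSchema, record: StatementRecord) -> None:
    """Raise if ``record`` violates ``schema`` (constraint kinds, datatype
    lexical validity, required positions, cardinalities, contiguous order
    ranks, certainty range)."""
    if record.type_iri != schema.type_iri:
        raise BindingError(
            f"record instantiates {record.type_iri}, schema defines "
            f"{schema.type_iri}")
    if not record.subject_bindings:
        raise MissingRequiredPositionError(schema.subject_position.role_label)
    subj = schema.subject_position
    if subj.max_values is not None and len(record.subject_bindings) > subj.max_values:
        raise CardinalityError(subj.role_label, len(record.subject_bindings),
                               subj.max_values)
    for b in record.subject_bindings:
        _check_binding(subj, b)
    _check_ranks(subj.role_label, record.subject_bindings)
    known = set(schema.roles)
    for role in record.bindings:
        if role not in known:
            raise UnknownRoleError(role)
    for p in schema.object_positions:
        vals = record.values(p.role_label)
        if p.required and not vals:
            raise MissingRequiredPositionError(p.role_label)
        if p.max_values is not None and len(vals) > p.max_values:
            raise CardinalityError(p.role_label, len(vals), p.max_values)
        for b in vals:
            _check_binding(p, b)
        if vals:
            _check_ranks(p.role_label, vals)
    if record.certainty is not None and not (0.0 <= record.certainty <= 1.0):
        raise BindingError(
            f"certainty {record.certainty} outside [0, 1]")


def _check_ranks(role: str, bindings: Sequence[ValueBinding]) -> None:
    ranks = sorted(b.order_rank for b in bindings)
    if ranks != list(range(1, len(bindings) + 1)):
        raise BindingError(
            f"order ranks {ranks} in position {role!r} are not contiguous 1..k")


def create_statement(
    schema: StatementTypeSchema,
    subject_bindings: Union[ValueBinding, Sequence[ValueBinding]],
    bindings: Mapping[str, Union[ValueBinding, Sequence[ValueBinding]]],
    metadata: Optional[ProvenanceMetadata] = None,
    *,
    negated: bool = False,
    certainty: Optional[float] = None,
    context_iri: Optional[str] = None,
    minter: Optional[IriMinter] = None,
) -> StatementRecord:
    """Create a validated token statement of ``schema``'s type.

    Bindings may be given as a single :class:`ValueBinding` or a sequence;
    multi-value bindings receive contiguous order ranks in the given order.
    All constraint and cardinality checks are applied; the statement IRI is
    minted (UUIDv4 under the minter's base namespace).
    """
    issues = validate_type_schema(schema)
    if issues:
        raise SchemaError(
            f"schema {schema.type_iri} is invalid: {issues[0].message}")
    minter = minter or IriMinter()

    def fill_class(position: PositionSpec, vals):
        # resource values default to the position's constraint class so the
        # serialized graph is self-contained for class-constraint checking
        if position.constraint.kind != "resource":
            return vals
        return tuple(
            replace(b, resource_class=position.constraint.value_class)
            if b.is_resource and b.resource_class is None else b
            for b in vals)

    subj = (subject_bindings,) if isinstance(subject_bindings, ValueBinding) \
        else tuple(subject_bindings)
    subj = fill_class(schema.subject_position, subj)
    norm: Dict[str, Tuple[ValueBinding, ...]] = {}
    for role, val in bindings.items():
        vals = (val,) if isinstance(val, ValueBinding) else tuple(val)
        if vals:
            if role in set(schema.roles):
                vals = fill_class(schema.position(role), vals)
            norm[role] = _rank(vals)
    record = StatementRecord(
        statement_iri=minter.mint("statement"),
        type_iri=schema.type_iri,
        subject_bindings=_rank(subj),
        bindings=norm,
        negated=negated,
        certainty=certainty,
        context_iri=context_iri,
        provenance=metadata or ProvenanceMetadata(),
    )
    check_record(schema, record)
    return record


class SchemaRegistry:
    """Resolves statement-type IRIs to their schemata during parsing."""

    def __init__(self, schemas: Iterable[StatementTypeSchema] = ()):
        self._by_iri: Dict[str, StatementTypeSchema] = {}
        for s in schemas:
            self.add(s)

    def add(self, schema: StatementTypeSchema) -> None:
        self._by_iri[schema.type_iri] = schema

    def get(self, type_iri: str) -> Optional[StatementTypeSchema]:
        return self._by_iri.get(type_iri)

    def __contains__(self, type_iri: str) -> bool:
        return type_iri in self._by_iri

    def __iter__(self):
        return iter(self._by_iri.values())

    def __len__(self):
        return len(self._by_iri)
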