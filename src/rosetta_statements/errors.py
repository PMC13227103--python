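"""Exception hierarchy.

All errors raised by this package derive from :class:`RosettaError` so callers
can catch one type at an API boundary.  Validation of statement *types* is
reported as data (see :func:`rosetta_statements.model.validate_type_schema`);
exceptions are reserved for operations that cannot return a partial result.
"""


class RosettaError(Exception):
    """Base class for all package errors."""


class SchemaError(RosettaError):
    """A statement-type schema is structurally invalid."""


class DuplicateRoleError(SchemaError):
    """Two positions in one schema share a role label."""

    def __init__(self, role_label: str):
        self.role_label = role_label
        super().__init__(f"duplicate role label: {role_label!r}")


class UnknownRoleError(RosettaError):
    """A role label does not exist in the schema."""

    def __init__(self, role_label: str):
        self.role_label = role_label
        super().__init__(f"unknown role label: {role_label!r}")


class UnknownDatatypeError(RosettaError):
    """An editor datatype name is not in the supported set."""


class BindingError(RosettaError):
    """A statement binding violates its position's constraint."""


class MissingRequiredPositionError(BindingError):
    def __init__(self, role_label: str):
        self.role_label = role_label
        super().__init__(f"required position {role_label!r} has no binding")


class CardinalityError(BindingError):
    def __init__(self, role_label: str, got: int, allowed: int):
        self.role_label = role_label
        super().__init__(
            f"position {role_label!r} allows at most {allowed} value(s), got {got}"
        )


class DatatypeLexicalError(BindingError):
    def __init__(self, role_label: str, lexical: str, datatype: str):
        self.role_label = role_label
        self.lexical = lexical
        super().__init__(
            f"value {lexical!r} in position {role_label!r} is not a valid {datatype}"
        )


class GraphParseError(RosettaError):
    """An RDF graph does not follow the expected metamodel structure."""


class AnchorDeletedError(RosettaError):
    """The anchor statement resource has been soft-deleted."""


class AllVersionsDeletedError(RosettaError):
    """Every version of an anchor has been soft-deleted."""


class AlreadyDeletedError(RosettaError):
    """Attempt to soft-delete a record twice."""


class NotModifiableError(RosettaError):
    """Attempt to update an anchor whose metadata marks it unmodifiable."""


class RenderError(RosettaError):
    """A statement cannot be rendered with the given display template."""


class CrosswalkError(RosettaError):
    """A cross-walk specification cannot be applied to a statement."""


class UnmappedEntityError(CrosswalkError):
    def __init__(self, iri: str, role_label: str):
        self.iri = iri
        self.role_label = role_label
        super().__init__(
            f"no entity mapping for {iri} bound in position {role_label!r}"
        )


class QueryError(RosettaError):
    """A slot query is inconsistent with the statement-type schema."""
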