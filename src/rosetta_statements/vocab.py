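"""The statement-metamodel RDF vocabulary.

Every statement, whichever dialect it is serialized in, uses one small fixed
set of classes and properties.  Statement *types* contribute their own class
IRIs (one ontology class per verb/predicate, plus one object-position class
per slot in the full dialect), but the linking properties — ``subject``, the
numbered object-position property families, ``has version``, ``order``,
soft-delete markers and so on — are shared across all statement types.  That
uniformity is what makes generic tooling (shape generation, query generation,
faceting) possible.

The canonical namespace of the vocabulary is not fixed by any registry yet,
so it is configurable; the default under ``w3id.org`` is provisional.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Optional

from rdflib import Graph, Literal, Namespace, RDF, RDFS, URIRef
from rdflib.namespace import OWL

DEFAULT_NAMESPACE = "https://w3id.org/rosetta-statement/terms/"

#: Boolean annotation properties for per-position logical characteristics.
#: The set is open; these are the documented names.
KNOWN_LOGICAL_PROPERTIES = ("transitive", "symmetric", "reflexive", "functional")

_POSITION_PROP_RE = re.compile(
    r"^(required|optional)(Literal)?ObjectPosition(\d+)?$"
)


@dataclass(frozen=True)
class PositionPropertyInfo:
    """Decoded meaning of one member of the object-position property families."""

    required: bool
    literal: bool
    index: Optional[int]  # None for the unnumbered full-dialect link properties


@dataclass(frozen=True)
class RosettaVocabulary:
    """All terms of the statement metamodel under one namespace."""

    namespace: str = DEFAULT_NAMESPACE
    _ns: Namespace = field(init=False, repr=False, compare=False, default=None)

    def __post_init__(self):
        object.__setattr__(self, "_ns", Namespace(self.namespace))

    def term(self, local: str) -> URIRef:
        return self._ns[local]

    # --- classes -----------------------------------------------------------
    @property
    def Statement(self) -> URIRef:
        """Root class of which every statement-type class is a subclass."""
        return self.term("Statement")

    @property
    def Negation(self) -> URIRef:
        """Statements typed into this class are asserted to be negated."""
        return self.term("Negation")

    @property
    def SubjectPosition(self) -> URIRef:
        """Shared class of subject-position instances (full dialect)."""
        return self.term("SubjectPosition")

    # --- linking properties ------------------------------------------------
    @property
    def subject(self) -> URIRef:
        return self.term("subject")

    def position_property(
        self, required: bool, literal: bool, index: Optional[int] = None
    ) -> URIRef:
        """A member of the object-position property families.

        With ``index`` this is a numbered light-dialect property
        (e.g. ``requiredLiteralObjectPosition2``); without, the unnumbered
        full-dialect link property (``requiredObjectPosition`` /
        ``optionalObjectPosition`` — position instances, not values, are the
        objects there, so the literal/resource split does not apply).
        """
        name = "required" if required else "optional"
        if index is not None and literal:
            name += "Literal"
        name += "ObjectPosition"
        if index is not None:
            name += str(index)
        return self.term(name)

    @property
    def hasObjectPosition(self) -> URIRef:
        """Single link property of the simplified full dialect (no
        argument/adjunct distinction)."""
        return self.term("hasObjectPosition")

    def decode_position_property(self, pred: URIRef) -> Optional[PositionPropertyInfo]:
        """Inverse of :meth:`position_property`; ``None`` if ``pred`` is not a
        member of the families."""
        s = str(pred)
        if not s.startswith(self.namespace):
            return None
        m = _POSITION_PROP_RE.match(s[len(self.namespace):])
        if m is None:
            return None
        return PositionPropertyInfo(
            required=m.group(1) == "required",
            literal=m.group(2) is not None,
            index=int(m.group(3)) if m.group(3) else None,
        )

    # --- anchor / version properties ---------------------------------------
    @property
    def hasVersion(self) -> URIRef:
        return self.term("hasVersion")

    @property
    def hasDataSchema(self) -> URIRef:
        return self.term("hasDataSchema")

    @property
    def hasContext(self) -> URIRef:
        return self.term("hasContext")

    @property
    def hasStatement(self) -> URIRef:
        """Inverse of :attr:`hasContext`."""
        return self.term("hasStatement")

    @property
    def order(self) -> URIRef:
        return self.term("order")

    @property
    def versionNumber(self) -> URIRef:
        return self.term("versionNumber")

    @property
    def versionIdentifier(self) -> URIRef:
        """Opaque external identifier of a version (could be a DOI)."""
        return self.term("versionIdentifier")

    # --- metadata properties -----------------------------------------------
    @property
    def deletedAt(self) -> URIRef:
        return self.term("deletedAt")

    @property
    def deletedBy(self) -> URIRef:
        return self.term("deletedBy")

    @property
    def certainty(self) -> URIRef:
        return self.term("certainty")

    @property
    def creator(self) -> URIRef:
        return self.term("creator")

    @property
    def createdAt(self) -> URIRef:
        return self.term("createdAt")

    @property
    def author(self) -> URIRef:
        return self.term("author")

    @property
    def extractionMethod(self) -> URIRef:
        return self.term("extractionMethod")

    @property
    def importedFrom(self) -> URIRef:
        return self.term("importedFrom")

    @property
    def modifiable(self) -> URIRef:
        return self.term("modifiable")

    def logical_property(self, name: str) -> URIRef:
        """Boolean annotation property for a logical characteristic
        (e.g. ``transitive``)."""
        if not re.match(r"^[A-Za-z][A-Za-z0-9_-]*$", name):
            raise ValueError(f"not a valid logical property name: {name!r}")
        return self.term(name)

    # --- self description ---------------------------------------------------
    _CLASS_TERMS = ("Statement", "Negation", "SubjectPosition")
    _PROPERTY_TERMS = (
        "subject", "hasObjectPosition", "hasVersion", "hasDataSchema",
        "hasContext", "hasStatement", "order", "versionNumber",
        "versionIdentifier", "deletedAt", "deletedBy", "certainty", "creator",
        "createdAt", "author", "extractionMethod", "importedFrom", "modifiable",
    )

    def ontology_graph(self, max_index: int = 10) -> Graph:
        """A self-describing ontology graph of the vocabulary.

        The numbered object-position families are open-ended; the first
        ``max_index`` members of each family are materialized.
        """
        g = Graph()
        g.bind("rosetta", self._ns)
        for name in self._CLASS_TERMS:
            t = self.term(name)
            g.add((t, RDF.type, OWL.Class))
            g.add((t, RDFS.label, Literal(_humanize(name))))
        props = list(self._PROPERTY_TERMS)
        for i in range(1, max_index + 1):
            for required in (True, False):
                for literal in (True, False):
                    props.append(
                        str(self.position_property(required, literal, i))
                        [len(self.namespace):]
                    )
        for required in (True, False):
            props.append(
                str(self.position_property(required, literal=False))
                [len(self.namespace):]
            )
        for name in KNOWN_LOGICAL_PROPERTIES:
            props.append(name)
        for name in props:
            t = self.term(name)
            g.add((t, RDF.type, RDF.Property))
            g.add((t, RDFS.label, Literal(_humanize(name))))
        return g


def _humanize(local: str) -> str:
    """``hasDataSchema`` -> ``has data schema``."""
    out = re.sub(r"(?<=[a-z])(?=[A-Z])", " ", local)
    out = re.sub(r"(?<=[a-zA-Z])(?=\d)", " ", out)
    return out.lower() if local[0].islower() else out


#: Module-level default vocabulary instance.
DEFAULT_VOCAB = RosettaVocabulary()
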