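"""Nanopublication export.

Each statement *version* can be published as its own nanopublication: four
named graphs under one nanopub IRI.  The *head* graph declares the
nanopublication and links it to the other three; the *assertion* graph is
the version's statement graph with no metadata attached; metadata is split
by what it is about — claims about the assertion itself (certainty, the
author of the claim, the extraction method, the imported-from source, the
context publication) go to the *provenance* graph, while metadata about the
nanopublication as a publication act (creator, creation date, version
number and citable version identifier) goes to the *publication info*
graph.
"""

from __future__ import annotations

from dataclasses import dataclass

from rdflib import Dataset, Graph, Literal, Namespace, RDF, URIRef
from rdflib.namespace import PROV, XSD

from .errors import AlreadyDeletedError, RosettaError
from .full import AnchorRecord, VersionRecord, _version_triples
from .model import StatementTypeSchema
from .vocab import DEFAULT_VOCAB, RosettaVocabulary

NP = Namespace("http://www.nanopub.org/nschema#")

#: Predicates that carry metadata rather than assertion content.
_METADATA_LOCALS = (
    "versionNumber", "versionIdentifier", "creator", "createdAt", "author",
    "certainty", "deletedAt", "deletedBy", "extractionMethod", "importedFrom",
    "modifiable",
)


@dataclass(frozen=True)
class NanopubBundle:
    """One nanopublication: the dataset holding its four named graphs."""

    nanopub_iri: str
    dataset: Dataset

    @property
    def head_iri(self) -> str:
        return self.nanopub_iri + "#head"

    @property
    def assertion_iri(self) -> str:
        return self.nanopub_iri + "#assertion"

    @property
    def provenance_iri(self) -> str:
        return self.nanopub_iri + "#provenance"

    @property
    def pubinfo_iri(self) -> str:
        return self.nanopub_iri + "#pubinfo"

    def graph(self, iri: str) -> Graph:
        return self.dataset.graph(URIRef(iri))

    @property
    def named_graphs(self):
        return [g for g in self.dataset.graphs()
                if len(g) and str(g.identifier) != "urn:x-rdflib:default"]

    def to_trig(self) -> str:
        return self.dataset.serialize(format="trig")


def export_nanopub(
    version: VersionRecord,
    anchor: AnchorRecord,
    schema: StatementTypeSchema,
    vocab: RosettaVocabulary = DEFAULT_VOCAB,
) -> NanopubBundle:
    """Export one statement version as a nanopublication (TriG).

    The assertion graph equals the version's full-dialect graph minus every
    metadata triple; assertion and metadata triple sets are disjoint by
    construction.  Soft-deleted versions cannot be exported.
    """
    if version.is_deleted:
        raise AlreadyDeletedError(
            f"version {version.version_iri} is soft-deleted and cannot be "
            "published")
    if version not in anchor.versions:
        raise RosettaError(
            f"version {version.version_iri} does not belong to anchor "
            f"{anchor.anchor_iri}")
    np_iri = version.version_iri + "/nanopub"
    ds = Dataset()
    ds.bind("np", NP)
    ds.bind("rosetta", vocab.namespace)
    ds.bind("xsd", XSD)
    np = URIRef(np_iri)
    head = ds.graph(URIRef(np_iri + "#head"))
    assertion = ds.graph(URIRef(np_iri + "#assertion"))
    provenance = ds.graph(URIRef(np_iri + "#provenance"))
    pubinfo = ds.graph(URIRef(np_iri + "#pubinfo"))

    head.add((np, RDF.type, NP.Nanopublication))
    head.add((np, NP.hasAssertion, assertion.identifier))
    head.add((np, NP.hasProvenance, provenance.identifier))
    head.add((np, NP.hasPublicationInfo, pubinfo.identifier))

    metadata_preds = {vocab.term(local) for local in _METADATA_LOCALS}
    for s, p, o in _version_triples(version, anchor, schema, vocab):
        if p not in metadata_preds:
            assertion.add((s, p, o))

    a = assertion.identifier
    rec = version.record
    # the assertion always records which graph resource it was derived from
    provenance.add((a, PROV.wasDerivedFrom, URIRef(version.version_iri)))
    if rec.certainty is not None:
        provenance.add((a, vocab.certainty,
                        Literal(str(rec.certainty), datatype=XSD.decimal)))
    if rec.provenance.author is not None:
        provenance.add((a, vocab.author, Literal(rec.provenance.author)))
    if anchor.metadata.extraction_method is not None:
        provenance.add((a, vocab.extractionMethod,
                        Literal(anchor.metadata.extraction_method)))
    if anchor.metadata.imported_from is not None:
        provenance.add((a, vocab.importedFrom,
                        Literal(anchor.metadata.imported_from)))
    if anchor.context_iri is not None:
        provenance.add((a, vocab.hasContext, URIRef(anchor.context_iri)))

    pubinfo.add((np, vocab.versionNumber,
                 Literal(str(version.version_number), datatype=XSD.integer)))
    if version.external_id is not None:
        pubinfo.add((np, vocab.versionIdentifier,
                     Literal(version.external_id)))
    if rec.provenance.creator is not None:
        pubinfo.add((np, vocab.creator, Literal(rec.provenance.creator)))
    if rec.provenance.created_at is not None:
        pubinfo.add((np, vocab.createdAt,
                     Literal(rec.provenance.created_at,
                             datatype=XSD.dateTime)))
    return NanopubBundle(nanopub_iri=np_iri, dataset=ds)
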