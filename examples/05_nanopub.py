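"""Publish a statement version as a nanopublication.

Each version becomes its own nanopublication: four named graphs (head,
assertion, provenance, publication info).  The assertion graph is the
version's content with no metadata; metadata is split between provenance
(about the claim) and publication info (about the publication act).
"""

from rosetta_statements import (
    IriMinter,
    create_anchor,
    export_nanopub,
    make_fixtures,
)

corpus = make_fixtures(seed=0)
st = corpus.statement("ci_apple")
schema = corpus.schema_for(st)
anchor = create_anchor(st.record, schema, minter=IriMinter(seed=1))

bundle = export_nanopub(anchor.versions[0], anchor, schema)
print("nanopub IRI:", bundle.nanopub_iri)
print("named graphs:", len(bundle.named_graphs))
for g in bundle.named_graphs:
    print(f"  {str(g.identifier).rsplit('#', 1)[-1]}: {len(g)} triples")
print()
print(bundle.to_trig())
# Exactly four graphs; the assertion carries only statement content, so
# the claim can be cited and reused independently of its bookkeeping.
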