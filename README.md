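# rosetta-statements

Statement-centric construction of FAIR knowledge graphs.

Open, collaboratively curated knowledge graphs (research knowledge graphs
in particular) face a tension: semantic data schemata that model a
mind-independent reality (OBI- or OBOE-style measurement graphs, for
example) are good for reasoning but hard for domain experts to author,
read and query, while free-form triple entry produces content that is not
interoperable at all.  This package implements a middle path — the
*Rosetta Statement* approach — in which the unit of knowledge is a reified
n-ary statement modelled on a simple English sentence:

```
This apple  has a weight of  241.68  grams
SUBJECT     VERB             VALUE   UNIT
```

A **statement type** is an ontology class defined by its verb/predicate
together with a schema of syntactic positions: one subject position and
ordered object positions, each with a thematic role label (`QUALITY`,
`UNIT`, …), an argument/adjunct flag (required vs optional), a cardinality
bound, display texts, and a constraint — an ontology class for resource
positions or an XSD datatype (optionally with pattern/range) for literal
positions.  Token statements instantiate the class and bind the positions.
Because every type shares one small metamodel vocabulary, the machinery
around it is generic:

- **Two RDF dialects.** The *light* dialect links subject and objects
  directly to the statement resource via numbered position properties
  (`rosetta:requiredLiteralObjectPosition1`, …): the basic weight
  measurement above costs 3 slot-linking triples instead of the 5–6 of
  reality-modelling schemata.  The *full* dialect adds an anchor resource,
  append-only version resources and per-value position instances, giving
  versioning, per-position edit history, value order, certainty, negation,
  logical-property annotation and FAIR soft delete (metadata stays
  accessible after deletion).  TriG/N-Quads output puts each version in
  its own named graph.
- **Dynamic labels.** Sentence templates derived from the schema render
  any statement back into English, dropping empty optional slots together
  with their pre/post texts; mind-map patterns render statements as
  labelled node/edge graphs merged on shared resources.
- **SHACL shapes.** Each type compiles to a SHACL shape (the shape IRI is
  the schema IRI); an in-package validator for the emitted SHACL fragment
  checks statement graphs and names the offending position paths.
- **Nanopublications.** Each statement version exports as a
  nanopublication: head, metadata-free assertion, provenance and
  publication-info named graphs.
- **Schema cross-walks.** Declarative mappings re-emit statements in
  other schemata — built-in OBI-style (5 slot-path triples), OBOE-style
  (6) and tabular targets with entity maps translating term IRIs.
- **Slot-form queries.** A filled slot form compiles to SPARQL (resolving
  only current, non-deleted versions in the full dialect) and every
  position of a type becomes a facet.

## Worked example

```python
from rosetta_statements import (
    ConstraintSpec, PositionSpec, ValueBinding,
    create_statement, define_statement_type,
    derive_label_template, render_label,
)

schema = define_statement_type(
    label="has weight", verb_display="has a weight of",
    subject_spec=PositionSpec(
        role_label="MATERIAL ENTITY", preposition_text="This ",
        constraint=ConstraintSpec.resource(
            "http://purl.obolibrary.org/obo/BFO_0000040")),
    object_specs=[
        PositionSpec(role_label="VALUE", preposition_text=" ",
                     constraint=ConstraintSpec.literal("float")),
        PositionSpec(role_label="UNIT", preposition_text=" ",
                     constraint=ConstraintSpec.resource(
                         "http://purl.obolibrary.org/obo/UO_0000000")),
    ])

record = create_statement(
    schema,
    ValueBinding.resource("https://example.org/kg/entity/apple-1", "apple",
                          resource_class="http://www.wikidata.org/entity/Q89"),
    {"VALUE": ValueBinding.literal("241.68", "float"),
     "UNIT": ValueBinding.resource("http://www.wikidata.org/entity/Q41803",
                                   "grams")})

template = derive_label_template(schema)
print(template.to_string())
print(render_label(template, record, schema))
```

prints

```
This MATERIAL ENTITY has a weight of VALUE UNIT
This apple has a weight of 241.68 grams
```

— the first line is the sentence template derived from the type, the
second the token statement rendered through it, reproducing the captured
lexical form `241.68` verbatim.  The same record serializes to a light
graph with exactly 3 slot-linking triples (`count_slot_triples`), conforms
to the generated SHACL shape, and cross-walks into an OBI-style graph of 5
slot-path triples.

The `examples/` directory holds one short script per capability
(definition/rendering, light dialect, versioning, shapes, nanopubs,
cross-walks, queries/facets); each prints what it computes with a line on
what the numbers mean.  A thin CLI mirrors the library
(`rosetta type|stmt|shape|nanopub|crosswalk|query|fixtures …`).

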