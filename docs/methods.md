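# Methods

## The statement metamodel

The package models assertional natural-language statements rather than a
mind-independent reality.  A statement type is fixed by its verb/predicate
and a syntactic frame: a subject position and ordered object positions.
Positions carry thematic role labels, an argument/adjunct distinction
(required vs optional), a cardinality bound (`max_values`, `None` =
unbounded), display texts (preposition/postposition), and a constraint.
Resource constraints name an ontology class whose instances (or instances
of asserted subclasses) are admissible; literal constraints name one of
eight editor datatypes (`text`, `URL`, `date`, `datetime`, `boolean`,
`integer`, `decimal`, `float`) mapped onto XSD, optionally with a regex
pattern and an inclusive numeric range.  Constraint classes are opaque
IRIs: no term lookup or existence check is performed, by design.

Role labels are unique across the whole schema, subject included, because
the binding API addresses positions by role.  Where a natural frame
repeats a role ("PERSON met PERSON"), the second occurrence gets a
distinct label (`PERSON_2`).  Zero object positions are allowed
(intransitive verbs); a schema may later gain optional adjunct positions
without invalidating existing statements, which is why generated shapes
are open by default.

Certainty is a decimal in [0, 1]; no established value space exists for
statement-level certainty, so the unit interval was chosen as the least
surprising convention and is enforced at statement creation.

### IRIs

Type IRIs are slugged from labels (lowercase, hyphens) under a
configurable base; the vocabulary namespace defaults to a provisional
`w3id.org` prefix and is configurable because no canonical registration
exists.  Instance IRIs are UUIDv4-based, injective within a run and
reproducible under a fixed seed.  No blank nodes are used anywhere:
deterministic node identity is what makes canonical serialisation,
diffing and version comparison work.  Position-instance IRIs in the full
dialect are derived deterministically from the version IRI, role slug and
order rank, so re-serialising an unchanged anchor is byte-stable and an
update can only ever add triples.

## The two dialects

**Light.**  One statement resource, typed into its statement class (plus
a `Negation` class when negated), linked directly to values through
numbered properties from four families
(`{required,optional} × {resource,literal}`), where the number is the
position's index in template order, shared across families.  Whether
numbering should instead restart per family is an open design point; a
single shared index is used and documented here.
Value order is *not* representable (the dialect has no order property);
parsing assigns order ranks lexicographically, and
`canonicalize_value_order` states the exact round-trip contract.
Slot-triple counts exclude `rdf:type` triples: they classify rather than
link, which is how the basic measurement counts 3.

**Full.**  An anchor resource carries the statement's identity, its
`has data schema` link (resolving to the generated SHACL shape), an
optional `has context` link, and creation/import/modifiability/soft-delete
metadata.  Versions hang off the anchor via `has version` with
consecutive integer numbers; each version carries editor, timestamp,
certainty and an optional opaque external identifier (e.g. a DOI).
Metadata ownership is split single-owner: import source, modifiability
and anchor-level deletion live only on the anchor; editor, timestamp and
certainty only on versions.  The anchor never duplicates bindings.

Values are linked indirectly: one position instance per bound value,
typed into the shared subject-position class or the per-type object
position class (minted once per statement type, not per schema version),
holding the value via `rdf:value` and its rank via `order`.  One instance
per *value* (rather than one per position) is the package's resolution of
an underdetermined point: order and boolean logical-property annotations
need a resource to attach to, and literals cannot be triple subjects.
Versions link to instances through generic `requiredObjectPosition` /
`optionalObjectPosition` properties (role identity is carried by the
instance's class); a simplified single `hasObjectPosition` link is
available behind a flag.

Soft delete only adds `deleted at`/`deleted by` triples — at anchor or at
version level — and the retrieval API keeps returning metadata while
suppressing content, so accessibility of metadata survives deletion.
Anchors whose versions are all individually deleted are distinguished
from deleted anchors by separate error types.  Editing is strictly
sequential append; concurrent-editor conflict resolution is out of scope.

## Rendering

A dynamic label is derived as: subject slot, verb, object slots in index
order, each slot wrapped in its pre/postposition texts.  Pre/post texts
carry their own spacing and may *echo* another slot as `{ROLE}`; this is
how the measurement template prints the unit twice
(`… MAIN_VALUE UNIT (… LOWER_VALUE–UPPER_VALUE UNIT)`) while every role
occurs exactly once as a slot.  Rendering substitutes resource labels and
literal lexical forms verbatim (no numeric reformatting — `241.68` stays
`241.68`); a binding may carry a presentation-only `display_text`
("21st of April 2023" alongside the typed `2023-04-21`), which is not
part of the semantic content, is excluded from equality and is not
serialized to RDF.  Empty optional slots vanish together with their
pre/post texts; an empty required slot is unrenderable.  Multi-valued
slots join with serial comma and "and" in order-rank order.  Negation
rendering is unspecified upstream; the neutral prefix "It is not the case
that " was chosen.  The confidence-interval range dash is U+2013.
Verb display is a separate label from the type label (type "has
measurement" displays as "has"), and no verb agreement/inflection is
attempted — multilingual or inflected templates are out of scope.

Mind-map patterns emit one predicate node per statement and one node per
bound value, with role-labelled edges; resources merge across statements
by IRI, literals stay statement-scoped.  Exports are DOT and a JSON
node/edge list; no interactive visualisation.

## Shapes and validation

Light shapes target the statement class and hold one property shape per
position plus one for the subject path: `minCount` 1/0 from the
argument/adjunct flag, `maxCount` from the cardinality bound, `sh:class`
or `sh:datatype` (+pattern/range) from the constraint.  Full shapes
target version resources via `sh:targetSubjectsOf` on the version-number
property (anchors instantiate the same class but carry no bindings);
per-role cardinality uses qualified value shapes over the generic link
properties, value constraints sit on node shapes targeting the position
classes, and the subject's value class is checked through the sequence
path (subject, `rdf:value`).

`pyshacl` is not a dependency: validation is an in-package interpreter of
exactly the fragment the generator emits (target class/subjects-of,
predicate and sequence paths, min/max counts, class with
`rdfs:subClassOf*` closure over the *data* graph, datatype, pattern,
inclusive ranges, qualified value shapes, closedness).  No reasoner is
invoked; subclass admission works iff the hierarchy is asserted in the
data, which is why serialized resource values carry an `rdf:type` triple
(defaulting to the position's constraint class at creation) and the
fixture corpus ships an ontology graph with its class hierarchy and
labels.  Shapes are open; a closed mode (with ignored metadata
properties) is behind a flag because forward-compatible adjunct extension
argues against closing by default.

## Nanopublications and cross-walks

A version exports as four named graphs under
`<versionIRI>/nanopub#{head,assertion,provenance,pubinfo}`.  The
assertion is the version graph minus every metadata predicate (the two
triple sets are disjoint by construction).  Metadata splits by
aboutness: claims about the assertion (certainty, author of the claim,
extraction method, import source, context) go to provenance — which also
always records `prov:wasDerivedFrom` the version resource — while the
publication act (creator, timestamp, version number and citable
identifier) goes to publication info.  No publication to external
nanopub servers is attempted.

Cross-walks are declarative: minted intermediate nodes, a symbolic triple
pattern, an ordered column list for tabular targets, and an entity map.
The built-in OBI-style target (measurement datum → quality inhering in
the subject; datum → scalar value specification → numeric value and unit
label) has 5 slot-path triples; the OBOE-style target (observation →
entity; observation → measurement → characteristic, value node, standard)
has 6.  Which of the two patterns carries five and which six triples is
this package's own assignment, locked by golden tests.  The measured
quality is fixed by the basic measurement's statement type, so it enters
the cross-walk as a declarative constant (PATO weight for OBI-style, NCIT
weight for OBOE-style — the classic terminological split), not as a slot.
Graph targets are wrapped in a named graph whose IRI is the statement
resource; the tabular target instead puts the statement IRI in a
dedicated column.  Extraction inverts graph targets where the entity map
is bijective.  Slot-path triple counts exclude `rdf:type`, mirroring the
slot-triple count on the light dialect.

## Queries, store, facets

Slot queries compile to SPARQL 1.1: one graph pattern per filtered role,
with exact-resource, resource-class (`rdf:type/rdfs:subClassOf*`),
literal-equality and inclusive-range filters.  Full-dialect queries (the
default) resolve only current versions: non-deleted anchor, non-deleted
version, no newer non-deleted version.  Light-dialect queries exclude
anchors/versions (which instantiate the same type class) by filtering on
the full-dialect marker properties.  The in-memory store keeps records
and the merged graph side by side so generated queries are executable and
auditable against a brute-force pass over the records; facet counts tally
each bound value once per statement, keyed by the value's asserted label
(several apples labelled "apple" share a bucket) or IRI local name,
literals by lexical form.  There is no HTTP server or database backend.

## Synthetic corpus

`make_fixtures(seed, n_per_type)` is a pure function of its arguments.
It always contains the worked examples (the 241.68 g apple with 95% CI
241.31–242.05 g, the 212.45 g apple with CI 212.44–212.47 g, an orange
without CI, Anna's Berlin→Paris train journey, the four-city multi-value
variant with two subjects, and Sarah meeting Bob on 2021-07-04) and adds
`n_per_type` synthetic statements per type: fruit weights uniform in
[50, 500] with 2-decimal lexical forms, optional confidence intervals at
90/95/99%, travel itineraries over an eight-city pool with 0–3 via
stops, and meetings with occasional negation — magnitudes chosen to look
like the worked examples they sit beside.  All generated statements
validate against their schemata at construction and conform to their
generated shapes.  The generator emulates structural variety (optional
slots present/absent, multi-values, negation, certainty), not realistic
science: passing tests demonstrate metamodel correctness (round-trips,
shape soundness/sensitivity, oracle equality), not fitness of any
particular ontology binding.  Default problem size in the test suite and
acceptance script is 125 statements per type (≈500 synthetic statements),
which exercises every code path while keeping runs in seconds.

## Numerical and formatting choices

Literal lexical forms are stored and serialized unnormalized
(`normalize=False` in rdflib) so `165.30` survives a round-trip; datatype
validity is checked lexically per XSD type.  Canonical serialisation is
sorted N-Triples lines (a Turtle subset), chosen over prettier Turtle for
byte-stable diffs.  Timestamps are ISO-8601 strings typed `xsd:dateTime`
and compared as strings.  Range filters compare floats; date ranges rely
on ISO-8601's lexicographic ordering.

## Known limitations

- Light-dialect multi-value order is lossy by design; use the full
  dialect when order matters.
- Passive forms, tenses and syntactic alternations are not modelled.
- SHACL support covers exactly the generated fragment, not full SHACL,
  and no SHACL-SPARQL constraints.
- Entity maps are user-supplied tables; no live unit/term resolution.
- No concurrent editing, no reasoning (cross-walk outputs are produced
  for reasoning systems; none is run here).
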