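"""Generate a SHACL shape from a statement type and validate data with it.

Every statement type translates mechanically into a shape (the shape IRI
is the schema IRI the full dialect's has-data-schema points at); valid
graphs conform, and single-fault mutants are caught with a named path.
"""

from rdflib import Literal, URIRef

from rosetta_statements import (
    DEFAULT_VOCAB,
    generate_shape,
    make_fixtures,
    to_light_graph,
    validate_statement,
)

corpus = make_fixtures(seed=0)
st = corpus.statement("basic_apple")
schema = corpus.schema_for(st)
bundle = generate_shape(schema, dialect="light")
print("shape IRI:", bundle.shape_iri)
print("property shapes:", sorted(bundle.position_shapes))

data = to_light_graph(st.record, schema) + corpus.ontology_graph()
print("valid statement conforms:", validate_statement(data, bundle).conforms)

# mutate: serialize the value as a plain string instead of xsd:float
stmt = URIRef(st.record.statement_iri)
pred = DEFAULT_VOCAB.position_property(required=True, literal=True, index=1)
data.remove((stmt, pred, None))
data.add((stmt, pred, Literal("241.68")))
report = validate_statement(data, bundle)
print("mutant conforms:", report.conforms)
for v in report.violations:
    print(f"  {v.rule} at {v.path}: {v.message}")
# The datatype flip produces a violation naming the value position's path.
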