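"""Cross-walk a measurement statement into OBI-style, OBOE-style and
tabular targets.

Cross-walks give schema interoperability: the same captured content is
emitted in the measurement patterns other communities expect, with entity
mappings translating term IRIs (here, a general-vocabulary gram into the
units-ontology gram).
"""

from rosetta_statements import (
    apply_crosswalk,
    extract_from_crosswalk,
    make_fixtures,
    slot_path_triple_count,
)
from rosetta_statements.crosswalk import (
    obi_measurement_spec,
    oboe_measurement_spec,
    rows_to_csv,
    tabular_measurement_spec,
)
from rosetta_statements.fixtures import GRAM

PATO_WEIGHT = "http://purl.obolibrary.org/obo/PATO_0000128"
NCIT_WEIGHT = "http://purl.obolibrary.org/obo/NCIT_C25208"
UO_GRAM = "http://purl.obolibrary.org/obo/UO_0000021"

corpus = make_fixtures(seed=0)
st = corpus.statement("basic_apple")
schema = corpus.schema_for(st)
entity_map = {GRAM: UO_GRAM}

obi = apply_crosswalk(st.record,
                      obi_measurement_spec(schema, PATO_WEIGHT, entity_map),
                      schema)
oboe = apply_crosswalk(st.record,
                       oboe_measurement_spec(schema, NCIT_WEIGHT, entity_map),
                       schema)
print("OBI-style slot-path triples: ", slot_path_triple_count(obi.graph))
print("OBOE-style slot-path triples:", slot_path_triple_count(oboe.graph))
# 5 and 6 triples for content the light dialect stores in 3 — the
# intermediate nodes (measurement datum, value specification, observation,
# measurement) exist for reasoning, not for the human reader.

tab = apply_crosswalk(st.record, tabular_measurement_spec(schema, "weight"),
                      schema)
print()
print(rows_to_csv(list(tab.row), [tab.row]))
# The statement IRI gets a dedicated column so the row stays referencable.

subject, bindings = extract_from_crosswalk(
    obi, obi_measurement_spec(schema, PATO_WEIGHT, entity_map), schema)
print("inverse extraction:", subject,
      {k: v.resource_iri or v.lexical for k, v in bindings.items()})
# With a bijective entity map the OBI-style graph inverts back to the
# original bindings.
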