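"""Nanopublications, schema cross-walks, slot queries and facets."""

import pytest
from rdflib import Dataset, RDF, URIRef

from rosetta_statements import (
    IriMinter,
    ProvenanceMetadata,
    SlotFilter,
    SlotQuery,
    StatementStore,
    ValueBinding,
    apply_crosswalk,
    build_query,
    create_anchor,
    export_nanopub,
    extract_from_crosswalk,
    facet_counts,
    slot_path_triple_count,
    soft_delete,
    update_statement,
)
from rosetta_statements.crosswalk import (
    CrosswalkSpec,
    generic_tabular_spec,
    obi_measurement_spec,
    oboe_measurement_spec,
    rows_to_csv,
    tabular_measurement_spec,
)
from rosetta_statements.errors import (
    AlreadyDeletedError,
    CrosswalkError,
    QueryError,
    UnmappedEntityError,
)
from rosetta_statements.fixtures import GRAM, WEIGHT

PATO_WEIGHT = "http://purl.obolibrary.org/obo/PATO_0000128"
NCIT_WEIGHT = "http://purl.obolibrary.org/obo/NCIT_C25208"
UO_GRAM = "http://purl.obolibrary.org/obo/UO_0000021"


@pytest.fixture()
def apple_anchor(corpus, minter):
    st = corpus.statement("ci_apple")
    schema = corpus.schema_for(st)
    return schema, create_anchor(st.record, schema, minter=minter)


# ---------------------------------------------------------------------------
# nanopublications
# ---------------------------------------------------------------------------

class TestNanopub:
    def test_export_yields_exactly_four_named_graphs(self, apple_anchor):
        schema, anchor = apple_anchor
        bundle = export_nanopub(anchor.versions[0], anchor, schema)
        assert len(bundle.named_graphs) == 4
        ids = {str(g.identifier) for g in bundle.named_graphs}
        assert ids == {bundle.head_iri, bundle.assertion_iri,
                       bundle.provenance_iri, bundle.pubinfo_iri}

    def test_head_links_nanopub_to_other_three_graphs(self, apple_anchor):
        schema, anchor = apple_anchor
        bundle = export_nanopub(anchor.versions[0], anchor, schema)
        head = bundle.graph(bundle.head_iri)
        np = URIRef(bundle.nanopub_iri)
        linked = {str(o) for o in head.objects(np, None)
                  if str(o).startswith(bundle.nanopub_iri)}
        assert linked == {bundle.assertion_iri, bundle.provenance_iri,
                          bundle.pubinfo_iri}

    def test_assertion_is_metadata_free(self, apple_anchor):
        """Assertion = version graph minus metadata; the two triple sets
        are disjoint."""
        from rosetta_statements.full import _version_triples
        from rosetta_statements.vocab import DEFAULT_VOCAB
        schema, anchor = apple_anchor
        version = anchor.versions[0]
        bundle = export_nanopub(version, anchor, schema)
        assertion = set(bundle.graph(bundle.assertion_iri))
        full = set(_version_triples(version, anchor, schema, DEFAULT_VOCAB))
        metadata = full - assertion
        assert assertion <= full
        assert all(p in {DEFAULT_VOCAB.versionNumber, DEFAULT_VOCAB.creator,
                         DEFAULT_VOCAB.createdAt, DEFAULT_VOCAB.author,
                         DEFAULT_VOCAB.certainty,
                         DEFAULT_VOCAB.versionIdentifier}
                   for _s, p, _o in metadata)
        assert not (assertion & metadata)

    def test_two_versions_get_distinct_nanopub_iris(self, apple_anchor):
        schema, anchor = apple_anchor
        update_statement(anchor, schema,
                         {"MAIN_VALUE": ValueBinding.literal("241.0", "float")},
                         ProvenanceMetadata(creator="u2",
                                            created_at="2024-01-02T00:00:00"))
        b1 = export_nanopub(anchor.versions[0], anchor, schema)
        b2 = export_nanopub(anchor.versions[1], anchor, schema)
        assert b1.nanopub_iri != b2.nanopub_iri

    def test_deleted_version_cannot_be_published(self, apple_anchor):
        schema, anchor = apple_anchor
        soft_delete(anchor.versions[0], "mod", "2024-02-01T00:00:00")
        with pytest.raises(AlreadyDeletedError):
            export_nanopub(anchor.versions[0], anchor, schema)

    def test_trig_output_parses_back_to_four_graphs(self, apple_anchor):
        schema, anchor = apple_anchor
        bundle = export_nanopub(anchor.versions[0], anchor, schema)
        ds = Dataset()
        ds.parse(data=bundle.to_trig(), format="trig")
        assert sum(1 for g in ds.graphs() if len(g)
                   and str(g.identifier) != "urn:x-rdflib:default") == 4


# ---------------------------------------------------------------------------
# cross-walks
# ---------------------------------------------------------------------------

class TestCrosswalk:
    def _basic(self, corpus):
        st = corpus.statement("basic_apple")
        return st.record, corpus.schema_for(st)

    def test_obi_style_has_five_and_oboe_style_six_slot_path_triples(
            self, corpus):
        record, schema = self._basic(corpus)
        emap = {GRAM: UO_GRAM}
        obi = apply_crosswalk(record,
                              obi_measurement_spec(schema, PATO_WEIGHT, emap),
                              schema)
        oboe = apply_crosswalk(record,
                               oboe_measurement_spec(schema, NCIT_WEIGHT, emap),
                               schema)
        counts = {slot_path_triple_count(obi.graph),
                  slot_path_triple_count(oboe.graph)}
        assert counts == {5, 6}
        assert slot_path_triple_count(obi.graph) == 5
        assert slot_path_triple_count(oboe.graph) == 6

    def test_unit_iri_passes_through_the_entity_map(self, corpus):
        record, schema = self._basic(corpus)
        obi = apply_crosswalk(
            record, obi_measurement_spec(schema, PATO_WEIGHT, {GRAM: UO_GRAM}),
            schema)
        assert (None, None, URIRef(UO_GRAM)) in obi.graph
        assert (None, None, URIRef(GRAM)) not in obi.graph

    def test_missing_entity_mapping_for_constrained_slot_is_rejected(
            self, corpus):
        record, schema = self._basic(corpus)
        with pytest.raises(UnmappedEntityError, match="UNIT"):
            apply_crosswalk(record,
                            obi_measurement_spec(schema, PATO_WEIGHT, {}),
                            schema)

    def test_unmapped_required_role_is_rejected_naming_the_role(self, corpus):
        record, schema = self._basic(corpus)
        spec = CrosswalkSpec(
            source_type_iri=schema.type_iri, target="custom",
            nodes={"n": None},
            triples=(("node:n", "https://example.org/p/of", "subject"),))
        with pytest.raises(CrosswalkError, match="VALUE"):
            apply_crosswalk(record, spec, schema)

    def test_tabular_crosswalk_emits_statement_iri_column(self, corpus):
        record, schema = self._basic(corpus)
        result = apply_crosswalk(record,
                                 tabular_measurement_spec(schema, "weight"),
                                 schema)
        assert list(result.row) == ["statement_iri", "subject", "quality",
                                    "value", "unit"]
        assert result.row["statement_iri"] == record.statement_iri
        assert result.row == {**result.row, "subject": "apple",
                              "quality": "weight", "value": "241.68",
                              "unit": "grams"}

    def test_generic_tabular_layout_follows_schema_order(self, corpus):
        st = corpus.statement("meet_sarah")
        schema = corpus.schema_for(st)
        result = apply_crosswalk(st.record, generic_tabular_spec(schema),
                                 schema)
        assert list(result.row) == ["statement_iri", "subject", "person_2",
                                    "date"]
        csv_text = rows_to_csv(list(result.row), [result.row])
        assert csv_text.splitlines()[0] == "statement_iri,subject,person_2,date"

    def test_inverse_extraction_recovers_bindings(self, corpus):
        """With a bijective entity map, walking the OBI-style output
        backwards recovers the original subject and values."""
        record, schema = self._basic(corpus)
        spec = obi_measurement_spec(schema, PATO_WEIGHT, {GRAM: UO_GRAM})
        result = apply_crosswalk(record, spec, schema)
        subject, bindings = extract_from_crosswalk(result, spec, schema)
        assert subject == record.subject_bindings[0].resource_iri
        assert bindings["VALUE"].lexical == \
            record.values("VALUE")[0].lexical
        assert bindings["UNIT"].resource_iri == GRAM

    def test_all_bound_values_appear_in_graph_targets(self, corpus):
        record, schema = self._basic(corpus)
        emap = {GRAM: UO_GRAM}
        for spec in (obi_measurement_spec(schema, PATO_WEIGHT, emap),
                     oboe_measurement_spec(schema, NCIT_WEIGHT, emap)):
            g = apply_crosswalk(record, spec, schema).graph
            terms = {str(t) for tr in g for t in tr}
            assert record.values("VALUE")[0].lexical in \
                {str(o) for _s, _p, o in g}
            assert UO_GRAM in terms
            assert record.subject_bindings[0].resource_iri in terms

    def test_named_graph_wrapping_uses_statement_iri(self, corpus):
        record, schema = self._basic(corpus)
        result = apply_crosswalk(
            record,
            obi_measurement_spec(schema, PATO_WEIGHT, {GRAM: UO_GRAM}),
            schema)
        ds = Dataset()
        ds.parse(data=result.to_trig(), format="trig")
        named = [g for g in ds.graphs() if len(g)]
        assert [str(g.identifier) for g in named] == [record.statement_iri]


# ---------------------------------------------------------------------------
# queries and facets
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def light_store(corpus):
    store = StatementStore(corpus.registry())
    for st in corpus.statements:
        store.add_record(st.record)
    store.load_ontology(corpus.ontology_graph())
    return store


@pytest.fixture(scope="module")
def full_store(corpus):
    store = StatementStore(corpus.registry())
    minter = IriMinter(seed=77)
    anchors = []
    for st in corpus.statements:
        anchor = create_anchor(st.record, corpus.schema_for(st),
                               minter=minter)
        anchors.append((st, anchor))
        store.add_anchor(anchor)
    store.load_ontology(corpus.ontology_graph())
    store._test_anchors = anchors
    return store


class TestSlotQueries:
    def test_no_filters_returns_all_statements_of_the_type(self, corpus,
                                                           light_store):
        schema = corpus.schemas["measurement_ci"]
        got = light_store.run_slot_query(
            SlotQuery(schema.type_iri, {}, dialect="light"))
        want = sorted(st.record.statement_iri for st in corpus.statements
                      if st.schema_key == "measurement_ci")
        assert got == want

    def test_subject_class_filter_matches_brute_force(self, corpus,
                                                      light_store):
        from rosetta_statements.fixtures import APPLE_CLASS
        schema = corpus.schemas["measurement_ci"]
        got = light_store.run_slot_query(SlotQuery(
            schema.type_iri,
            {"MATERIAL ENTITY": SlotFilter.value_class(APPLE_CLASS)},
            dialect="light"))
        want = sorted(
            st.record.statement_iri for st in corpus.statements
            if st.schema_key == "measurement_ci"
            and any(b.resource_class == APPLE_CLASS
                    for b in st.record.subject_bindings))
        assert got == want and got

    def test_numeric_range_filter_matches_brute_force(self, corpus,
                                                      light_store):
        schema = corpus.schemas["measurement_ci"]
        got = light_store.run_slot_query(SlotQuery(
            schema.type_iri,
            {"MAIN_VALUE": SlotFilter.in_range(200, 300)}, dialect="light"))
        want = sorted(
            st.record.statement_iri for st in corpus.statements
            if st.schema_key == "measurement_ci"
            and any(200 <= float(b.lexical) <= 300
                    for b in st.record.values("MAIN_VALUE")))
        assert got == want

    def test_full_dialect_query_returns_anchors(self, corpus, full_store):
        schema = corpus.schemas["measurement_ci"]
        got = full_store.run_slot_query(SlotQuery(
            schema.type_iri, {"MAIN_VALUE": SlotFilter.in_range(200, 300)}))
        want = sorted(
            anchor.anchor_iri for st, anchor in full_store._test_anchors
            if st.schema_key == "measurement_ci"
            and any(200 <= float(b.lexical) <= 300
                    for b in st.record.values("MAIN_VALUE")))
        assert got == want

    def test_full_query_resolves_only_current_versions(self, corpus):
        """After an update moves the value out of range, the anchor no
        longer matches; old versions are invisible to queries."""
        schema = corpus.schemas["measurement_ci"]
        st = corpus.statement("ci_apple")
        store = StatementStore(corpus.registry())
        anchor = create_anchor(st.record, schema, minter=IriMinter(seed=5))
        update_statement(anchor, schema,
                         {"MAIN_VALUE": ValueBinding.literal("999.0", "float")},
                         ProvenanceMetadata(creator="u",
                                            created_at="2024-01-02T00:00:00"))
        store.add_anchor(anchor)
        store.load_ontology(corpus.ontology_graph())
        q = SlotQuery(schema.type_iri,
                      {"MAIN_VALUE": SlotFilter.in_range(200, 300)})
        assert store.run_slot_query(q) == []
        q2 = SlotQuery(schema.type_iri,
                       {"MAIN_VALUE": SlotFilter.in_range(900, 1000)})
        assert store.run_slot_query(q2) == [anchor.anchor_iri]

    def test_filter_on_unknown_role_is_rejected(self, corpus):
        from rosetta_statements.errors import UnknownRoleError
        schema = corpus.schemas["meet"]
        with pytest.raises(UnknownRoleError):
            build_query(SlotQuery(schema.type_iri,
                                  {"PLACE": SlotFilter.in_range(0, 1)}),
                        schema)

    def test_type_incompatible_filter_is_rejected(self, corpus):
        schema = corpus.schemas["meet"]
        with pytest.raises(QueryError, match="range"):
            build_query(SlotQuery(
                schema.type_iri,
                {"PERSON_2": SlotFilter.in_range(0, 1)}), schema)

    def test_generated_sparql_is_syntactically_valid(self, corpus):
        from rdflib.plugins.sparql import prepareQuery
        schema = corpus.schemas["travel"]
        for dialect in ("light", "full"):
            q = build_query(SlotQuery(
                schema.type_iri,
                {"DESTINATION_LOCATION": SlotFilter.exact_resource(
                    "http://www.wikidata.org/entity/Q90")},
                dialect=dialect), schema)
            prepareQuery(q)  # raises on malformed SPARQL


class TestFacets:
    def test_subject_facet_counts_match_record_tally(self, corpus,
                                                     light_store):
        from collections import Counter
        schema = corpus.schemas["measurement_ci"]
        fc = facet_counts(light_store, schema.type_iri, dialect="light")
        oracle = Counter()
        for st in corpus.statements:
            if st.schema_key != "measurement_ci":
                continue
            for b in st.record.subject_bindings:
                oracle[b.resource_label] += 1
        assert fc["MATERIAL ENTITY"] == dict(oracle)

    def test_multi_valued_positions_count_each_value_once(self, corpus,
                                                          light_store):
        from collections import Counter
        schema = corpus.schemas["travel"]
        fc = facet_counts(light_store, schema.type_iri, dialect="light")
        oracle = Counter()
        for st in corpus.statements:
            if st.schema_key != "travel":
                continue
            for b in st.record.values("VIA"):
                oracle[b.resource_label] += 1
        assert fc["VIA"] == dict(oracle)

    def test_empty_store_yields_empty_facets(self, corpus):
        store = StatementStore(corpus.registry())
        fc = facet_counts(store, corpus.schemas["meet"].type_iri)
        assert all(not counts for counts in fc.values())

    def test_full_and_light_facets_agree(self, corpus, light_store,
                                         full_store):
        schema = corpus.schemas["meet"]
        light = facet_counts(light_store, schema.type_iri, dialect="light")
        full = facet_counts(full_store, schema.type_iri, dialect="full")
        assert light == full
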