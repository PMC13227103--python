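"""Statement-type definition, validation and token-statement creation."""

import dataclasses

import pytest
from hypothesis import given, settings, strategies as st

from rosetta_statements import (
    ConstraintSpec,
    IriMinter,
    PositionSpec,
    ValueBinding,
    create_statement,
    define_statement_type,
    reorder_positions,
    validate_type_schema,
    xsd_datatype_for,
)
from rosetta_statements.errors import (
    BindingError,
    CardinalityError,
    DatatypeLexicalError,
    DuplicateRoleError,
    MissingRequiredPositionError,
    SchemaError,
    UnknownDatatypeError,
    UnknownRoleError,
)
from rosetta_statements.model import EDITOR_DATATYPES, XSD_NS
from rosetta_statements.rendering import derive_label_template


def _subject(role="THING", cls="https://example.org/cls/Thing"):
    return PositionSpec(role_label=role,
                        constraint=ConstraintSpec.resource(cls))


def _res(role, required=True, **kw):
    return PositionSpec(role_label=role, required=required,
                        constraint=ConstraintSpec.resource(
                            f"https://example.org/cls/{role}"), **kw)


def _lit(role, datatype="float", required=True, **kw):
    return PositionSpec(role_label=role, required=required,
                        constraint=ConstraintSpec.literal(datatype), **kw)


class TestXsdMapping:
    @pytest.mark.parametrize("editor,local", [
        ("float", "float"), ("text", "string"), ("date", "date"),
        ("URL", "anyURI"), ("datetime", "dateTime"), ("boolean", "boolean"),
        ("integer", "integer"), ("decimal", "decimal"),
    ])
    def test_editor_types_map_to_xsd(self, editor, local):
        assert xsd_datatype_for(editor) == XSD_NS + local

    def test_unknown_editor_type_is_rejected(self):
        with pytest.raises(UnknownDatatypeError):
            xsd_datatype_for("complex128")


class TestDefineStatementType:
    def test_measurement_type_has_expected_arity(self):
        schema = define_statement_type(
            "has measurement", "a measurement", [],
            _subject("MATERIAL ENTITY"),
            [_res("QUALITY"), _lit("MAIN_VALUE"), _lit("UPPER_VALUE", required=False),
             _lit("LOWER_VALUE", required=False),
             _lit("INTERVAL_VALUE", "decimal", required=False), _res("UNIT")])
        assert len(schema.object_positions) == 6
        assert len(schema.literal_positions) == 4
        assert [p.index for p in schema.object_positions] == [1, 2, 3, 4, 5, 6]
        assert validate_type_schema(schema) == []

    def test_intransitive_type_with_zero_objects(self):
        schema = define_statement_type("sleeps", subject_spec=_subject("PERSON"),
                                       object_specs=[])
        assert schema.object_positions == ()
        assert validate_type_schema(schema) == []

    def test_ternary_meet_type(self):
        schema = define_statement_type(
            "meets", subject_spec=_subject("PERSON"),
            object_specs=[_res("PERSON_2"), _lit("DATE", "date")])
        assert len(schema.object_positions) == 2

    def test_duplicate_role_is_rejected_naming_the_duplicate(self):
        with pytest.raises(DuplicateRoleError, match="UNIT"):
            define_statement_type("has measurement",
                                  subject_spec=_subject(),
                                  object_specs=[_res("UNIT"), _res("UNIT")])

    def test_literal_subject_is_rejected(self):
        with pytest.raises(SchemaError, match="resource"):
            define_statement_type("weighs", subject_spec=_lit("WEIGHT"),
                                  object_specs=[])

    def test_type_iri_is_slugged_from_label(self):
        schema = define_statement_type("has part!", subject_spec=_subject(),
                                       object_specs=[_res("PART")])
        assert schema.type_iri.endswith("/has-part")


class TestValidateTypeSchema:
    def test_duplicate_roles_reported_as_issue(self):
        schema = define_statement_type("x", subject_spec=_subject(),
                                       object_specs=[_res("A"), _res("B")])
        bad = dataclasses.replace(
            schema, object_positions=(
                schema.object_positions[0],
                dataclasses.replace(schema.object_positions[1],
                                    role_label="A")))
        issues = validate_type_schema(bad)
        assert [i.rule for i in issues] == ["unique-role-labels"]

    def test_literal_subject_reported_as_issue(self):
        schema = define_statement_type("x", subject_spec=_subject(),
                                       object_specs=[])
        bad = dataclasses.replace(
            schema, subject_position=dataclasses.replace(
                schema.subject_position,
                constraint=ConstraintSpec.literal("date")))
        rules = {i.rule for i in validate_type_schema(bad)}
        assert "subject-resource-kind" in rules

    def test_noncontiguous_indices_reported(self):
        schema = define_statement_type("x", subject_spec=_subject(),
                                       object_specs=[_res("A"), _res("B")])
        bad = dataclasses.replace(
            schema, object_positions=tuple(
                dataclasses.replace(p, index=p.index + 1)
                for p in schema.object_positions))
        assert any(i.rule == "contiguous-indices"
                   for i in validate_type_schema(bad))


class TestReorderPositions:
    def _schema(self):
        return define_statement_type(
            "travels", subject_spec=_subject("PERSON"),
            object_specs=[_res("FROM", required=False), _res("TO"),
                          _lit("WHEN", "date", required=False)])

    def test_identity_permutation_changes_nothing(self):
        schema = self._schema()
        assert reorder_positions(schema, ["FROM", "TO", "WHEN"]) == schema

    def test_reverse_order_reverses_template(self):
        schema = self._schema()
        rev = reorder_positions(schema, ["WHEN", "TO", "FROM"])
        t = derive_label_template(rev).to_string()
        assert t.index("WHEN") < t.index("TO") < t.index("FROM")
        assert [p.index for p in rev.object_positions] == [1, 2, 3]

    def test_incomplete_permutation_is_rejected(self):
        with pytest.raises(SchemaError, match="missing"):
            reorder_positions(self._schema(), ["FROM", "TO"])

    def test_unknown_label_is_rejected(self):
        with pytest.raises(SchemaError, match="unknown"):
            reorder_positions(self._schema(), ["FROM", "TO", "WHENCE"])


class TestCreateStatement:
    def _meas(self):
        return define_statement_type(
            "has weight", subject_spec=_subject("MATERIAL ENTITY"),
            object_specs=[_lit("VALUE"), _res("UNIT")])

    def test_valid_statement_with_optional_slots_empty(self):
        schema = define_statement_type(
            "has measurement", subject_spec=_subject("MATERIAL ENTITY"),
            object_specs=[_res("QUALITY"), _lit("MAIN_VALUE"),
                          _lit("LOWER_VALUE", required=False), _res("UNIT")])
        rec = create_statement(
            schema, ValueBinding.resource("https://x/apple1", "apple"),
            {"QUALITY": ValueBinding.resource("https://x/weight", "weight"),
             "MAIN_VALUE": ValueBinding.literal("241.68", "float"),
             "UNIT": ValueBinding.resource("https://x/gram", "gram")})
        assert rec.values("LOWER_VALUE") == ()
        assert rec.values("MAIN_VALUE")[0].lexical == "241.68"
        # untyped resource values inherit the position's constraint class
        assert rec.subject_bindings[0].resource_class == \
            "https://example.org/cls/Thing"

    def test_missing_required_position_names_the_role(self):
        schema = define_statement_type(
            "meets", subject_spec=_subject("PERSON"),
            object_specs=[_res("PERSON_2"), _lit("DATE", "date")])
        with pytest.raises(MissingRequiredPositionError, match="DATE"):
            create_statement(
                schema, ValueBinding.resource("https://x/sarah", "Sarah"),
                {"PERSON_2": ValueBinding.resource("https://x/bob", "Bob")})

    def test_invalid_lexical_form_names_position_and_value(self):
        with pytest.raises(DatatypeLexicalError, match="VALUE.*heavy|heavy.*VALUE"):
            create_statement(
                self._meas(), ValueBinding.resource("https://x/a"),
                {"VALUE": ValueBinding.literal("heavy", "float"),
                 "UNIT": ValueBinding.resource("https://x/gram")})

    def test_multi_value_bindings_get_contiguous_ranks(self):
        schema = define_statement_type(
            "travels", subject_spec=_subject("PERSON"),
            object_specs=[_res("TO"),
                          _res("VIA", required=False, max_values=None)])
        cities = [ValueBinding.resource(f"https://x/c{i}") for i in range(4)]
        rec = create_statement(
            schema, ValueBinding.resource("https://x/anna"),
            {"TO": ValueBinding.resource("https://x/paris"), "VIA": cities})
        assert [b.order_rank for b in rec.values("VIA")] == [1, 2, 3, 4]

    def test_exceeding_max_values_is_rejected(self):
        with pytest.raises(CardinalityError, match="UNIT"):
            create_statement(
                self._meas(), ValueBinding.resource("https://x/a"),
                {"VALUE": ValueBinding.literal("1.0", "float"),
                 "UNIT": [ValueBinding.resource("https://x/g"),
                          ValueBinding.resource("https://x/kg")]})

    def test_unknown_role_is_rejected(self):
        with pytest.raises(UnknownRoleError, match="COLOR"):
            create_statement(
                self._meas(), ValueBinding.resource("https://x/a"),
                {"VALUE": ValueBinding.literal("1.0", "float"),
                 "UNIT": ValueBinding.resource("https://x/g"),
                 "COLOR": ValueBinding.resource("https://x/red")})

    def test_certainty_outside_unit_interval_is_rejected(self):
        with pytest.raises(BindingError, match="certainty"):
            create_statement(
                self._meas(), ValueBinding.resource("https://x/a"),
                {"VALUE": ValueBinding.literal("1.0", "float"),
                 "UNIT": ValueBinding.resource("https://x/g")},
                certainty=1.5)


class TestIriMinting:
    def test_minting_is_injective_within_a_run(self):
        m = IriMinter(seed=5)
        iris = [m.mint() for _ in range(200)]
        assert len(set(iris)) == 200

    def test_minting_is_stable_under_a_fixed_seed(self):
        a = [IriMinter(seed=9).mint() for _ in range(5)]
        b = [IriMinter(seed=9).mint() for _ in range(5)]
        assert a == b
        assert a != [IriMinter(seed=10).mint() for _ in range(5)]


# ---------------------------------------------------------------------------
# property tests
# ---------------------------------------------------------------------------

_ROLES = st.lists(
    st.text(alphabet="ABCDEFGHIJKLMNOPQRSTUVWXYZ_", min_size=2, max_size=8),
    min_size=0, max_size=5, unique=True)


@st.composite
def schemas(draw):
    roles = draw(_ROLES)
    specs = []
    for role in roles:
        if draw(st.booleans()):
            c = ConstraintSpec.resource(f"https://example.org/cls/{role}")
        else:
            c = ConstraintSpec.literal(
                draw(st.sampled_from(sorted(EDITOR_DATATYPES))))
        specs.append(PositionSpec(
            role_label=role, constraint=c,
            required=draw(st.booleans()),
            max_values=draw(st.sampled_from([1, 2, 5, None]))))
    return define_statement_type(
        draw(st.text(alphabet="abcdefghij ", min_size=1, max_size=12)
             .filter(lambda s: s.strip())),
        subject_spec=PositionSpec(
            role_label="SUBJECT_ROLE",
            constraint=ConstraintSpec.resource("https://example.org/cls/S")),
        object_specs=specs)


@settings(max_examples=60, derandomize=True)
@given(schemas())
def test_defined_schemas_always_validate_clean(schema):
    """Generator–validator consistency: define_statement_type only emits
    schemata that validate_type_schema accepts."""
    assert validate_type_schema(schema) == []


_SAMPLE_LEXICALS = {
    "text": "hello", "URL": "https://example.org/x", "date": "2023-04-21",
    "datetime": "2023-04-21T10:00:00", "boolean": "true", "integer": "42",
    "decimal": "3.14", "float": "2.5",
}


def _fill(schema, rng_bool=True):
    bindings = {}
    for p in schema.object_positions:
        if not p.required:
            continue
        if p.constraint.kind == "resource":
            bindings[p.role_label] = ValueBinding.resource(
                f"https://example.org/i/{p.role_label.lower()}")
        else:
            bindings[p.role_label] = ValueBinding.literal(
                _SAMPLE_LEXICALS[p.constraint.datatype], p.constraint.datatype)
    return bindings


@settings(max_examples=60, derandomize=True)
@given(schemas(), st.data())
def test_single_fault_mutations_are_rejected(schema, data):
    """create_statement accepts a fully valid binding set and rejects every
    mutation that violates exactly one constraint."""
    subject = ValueBinding.resource("https://example.org/i/s")
    bindings = _fill(schema)
    record = create_statement(schema, subject, bindings)
    assert record.type_iri == schema.type_iri

    faults = []
    required = [p for p in schema.object_positions if p.required]
    if required:
        faults.append("drop-required")
    literals = [p for p in required if p.constraint.kind == "literal"
                and p.constraint.datatype != "text"]
    if literals:
        faults.append("bad-lexical")
    resources = [p for p in required if p.constraint.kind == "resource"]
    if resources:
        faults.append("literal-in-resource-slot")
    bounded = [p for p in required if p.max_values == 1]
    if bounded:
        faults.append("too-many-values")
    if not faults:
        return
    fault = data.draw(st.sampled_from(faults))
    mutated = dict(bindings)
    if fault == "drop-required":
        victim = data.draw(st.sampled_from(required))
        del mutated[victim.role_label]
    elif fault == "bad-lexical":
        victim = data.draw(st.sampled_from(literals))
        mutated[victim.role_label] = ValueBinding.literal(
            "certainly-not-a-" + victim.constraint.datatype,
            victim.constraint.datatype)
    elif fault == "literal-in-resource-slot":
        victim = data.draw(st.sampled_from(resources))
        mutated[victim.role_label] = ValueBinding.literal("oops", "text")
    else:
        victim = data.draw(st.sampled_from(bounded))
        mutated[victim.role_label] = [
            mutated[victim.role_label],
            ValueBinding.resource("https://example.org/i/extra")
            if victim.constraint.kind == "resource"
            else ValueBinding.literal(
                _SAMPLE_LEXICALS[victim.constraint.datatype],
                victim.constraint.datatype)]
    with pytest.raises(BindingError):
        create_statement(schema, subject, mutated)
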