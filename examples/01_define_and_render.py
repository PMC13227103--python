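"""Define a statement type and render token statements as sentences.

A statement type mirrors a simple English sentence: a subject position, a
verb, and ordered object positions with semantic-role constraints.  The
sentence template (dynamic label) is derived mechanically from the type.
"""

from rosetta_statements import (
    ConstraintSpec,
    PositionSpec,
    ValueBinding,
    create_statement,
    define_statement_type,
    derive_label_template,
    render_label,
)

schema = define_statement_type(
    label="has weight",
    verb_display="has a weight of",
    description="a weight measurement of a material entity",
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

template = derive_label_template(schema)
print("type IRI: ", schema.type_iri)
print("template: ", template.to_string())

record = create_statement(
    schema,
    ValueBinding.resource("https://example.org/kg/entity/apple-1", "apple",
                          resource_class="http://www.wikidata.org/entity/Q89"),
    {"VALUE": ValueBinding.literal("241.68", "float"),
     "UNIT": ValueBinding.resource("http://www.wikidata.org/entity/Q41803",
                                   "grams")})
print("sentence: ", render_label(template, record, schema))
# The template slots fill with the bound labels and lexical forms verbatim:
# the sentence shows exactly the captured value, 241.68, and its unit.
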