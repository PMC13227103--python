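"""Packaged worked examples and a seeded synthetic statement corpus.

Four statement types ship with the package:

``measurement``
    *has weight* — subject MATERIAL ENTITY, a float VALUE and a UNIT; the
    quality is fixed by the type.  Its light graph is the three-slot-triple
    worked example.
``measurement_ci``
    *has measurement* — QUALITY, MAIN_VALUE, UNIT plus an optional
    confidence interval (INTERVAL_VALUE, LOWER_VALUE, UPPER_VALUE; four
    literal object positions).
``travel``
    *travels* — optional TRANSPORTATION / DEPARTURE_LOCATION, required
    DESTINATION_LOCATION, an optional multi-valued VIA and an optional
    DATETIME.
``meet``
    *meets* — a second person and a date (exactly two object positions).

The corpus always contains the worked-example statements (the apple
weighing 241.68 g with 95% CI 241.31–242.05 g; the 212.45 g apple with CI
212.44–212.47 g; Anna travelling by train from Berlin to Paris on the 21st
of April 2023; Sarah meeting Bob on the 4th of July 2021) and, on top,
``n_per_type`` synthetic statements per type drawn from a seeded generator.
Generation is a pure function of (seed, n_per_type); every generated
statement validates against its schema and conforms to its generated
shape (given the corpus ontology graph, which asserts the class hierarchy
and class labels).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from random import Random
from typing import Dict, List, Optional, Tuple

from rdflib import Graph, Literal, RDFS, URIRef

from .light import canonical_turtle, to_light_graph
from .model import (
    ConstraintSpec,
    IriMinter,
    PositionSpec,
    ProvenanceMetadata,
    SchemaRegistry,
    StatementRecord,
    StatementTypeSchema,
    ValueBinding,
    create_statement,
    define_statement_type,
)

WD = "http://www.wikidata.org/entity/"
OBO = "http://purl.obolibrary.org/obo/"
EX = "https://example.org/kg/"

MATERIAL_ENTITY = OBO + "BFO_0000040"
QUALITY_CLASS = OBO + "BFO_0000019"
UNIT_CLASS = OBO + "UO_0000000"
PERSON_CLASS = WD + "Q215627"
LOCATION_CLASS = WD + "Q2221906"
TRANSPORT_CLASS = WD + "Q334166"

APPLE_CLASS = WD + "Q89"
ORANGE_CLASS = WD + "Q13191"
GRAM = WD + "Q41803"
KILOGRAM = WD + "Q11570"
WEIGHT = WD + "Q476572"
TRAIN = WD + "Q870"
BERLIN = WD + "Q64"
PARIS = WD + "Q90"

_CLASS_LABELS = {
    MATERIAL_ENTITY: "material entity",
    QUALITY_CLASS: "quality",
    UNIT_CLASS: "unit",
    PERSON_CLASS: "person",
    LOCATION_CLASS: "location",
    TRANSPORT_CLASS: "mode of transport",
    APPLE_CLASS: "apple",
    ORANGE_CLASS: "orange",
}

_SUBCLASSES = {
    APPLE_CLASS: MATERIAL_ENTITY,
    ORANGE_CLASS: MATERIAL_ENTITY,
}


# ---------------------------------------------------------------------------
# statement-type schemata
# ---------------------------------------------------------------------------

def measurement_schema() -> StatementTypeSchema:
    """Basic weight measurement: 'This MATERIAL ENTITY has a weight of
    VALUE UNIT'."""
    return define_statement_type(
        label="has weight",
        verb_display="has a weight of",
        description="a weight measurement of a material entity",
        examples=["This apple has a weight of 241.68 grams"],
        subject_spec=PositionSpec(
            role_label="MATERIAL ENTITY", preposition_text="This ",
            placeholder_text="measured object",
            constraint=ConstraintSpec.resource(MATERIAL_ENTITY),
            max_values=None),
        object_specs=[
            PositionSpec(role_label="VALUE", preposition_text=" ",
                         placeholder_text="value",
                         constraint=ConstraintSpec.literal("float")),
            PositionSpec(role_label="UNIT", preposition_text=" ",
                         placeholder_text="unit",
                         constraint=ConstraintSpec.resource(UNIT_CLASS)),
        ])


def measurement_ci_schema() -> StatementTypeSchema:
    """Measurement with optional 95%-style confidence interval: four
    literal object positions and two resource object positions."""
    return define_statement_type(
        label="has measurement",
        verb_display="has",
        description="a quality measurement with an optional confidence "
                    "interval",
        examples=["This apple has a weight of 241.68 grams "
                  "(95% conf. interval: 241.31–242.05 grams)"],
        subject_spec=PositionSpec(
            role_label="MATERIAL ENTITY", preposition_text="This ",
            placeholder_text="measured object",
            constraint=ConstraintSpec.resource(MATERIAL_ENTITY),
            max_values=None),
        object_specs=[
            PositionSpec(role_label="QUALITY", preposition_text=" a ",
                         postposition_text=" of",
                         placeholder_text="measured quality",
                         constraint=ConstraintSpec.resource(QUALITY_CLASS)),
            PositionSpec(role_label="MAIN_VALUE", preposition_text=" ",
                         placeholder_text="value",
                         constraint=ConstraintSpec.literal("float")),
            PositionSpec(role_label="UNIT", preposition_text=" ",
                         placeholder_text="unit",
                         constraint=ConstraintSpec.resource(UNIT_CLASS)),
            PositionSpec(role_label="INTERVAL_VALUE", required=False,
                         preposition_text=" (",
                         postposition_text="% conf. interval:",
                         placeholder_text="confidence level",
                         description="the confidence level of the interval, "
                                     "as a percentage",
                         constraint=ConstraintSpec.literal(
                             "decimal", minimum=0, maximum=100)),
            PositionSpec(role_label="LOWER_VALUE", required=False,
                         preposition_text=" ",
                         placeholder_text="lower bound",
                         constraint=ConstraintSpec.literal("float")),
            PositionSpec(role_label="UPPER_VALUE", required=False,
                         preposition_text="–",  # en dash range
                         postposition_text=" {UNIT})",
                         placeholder_text="upper bound",
                         constraint=ConstraintSpec.literal("float")),
        ])


def travel_schema() -> StatementTypeSchema:
    """'PERSON travels by TRANSPORTATION from DEPARTURE_LOCATION to
    DESTINATION_LOCATION via VIA on the DATETIME'."""
    return define_statement_type(
        label="travels",
        description="a person travelling between locations",
        examples=["Anna travels by train from Berlin to Paris on the "
                  "21st of April 2023"],
        subject_spec=PositionSpec(
            role_label="PERSON", placeholder_text="traveller",
            constraint=ConstraintSpec.resource(PERSON_CLASS),
            max_values=None),
        object_specs=[
            PositionSpec(role_label="TRANSPORTATION", required=False,
                         preposition_text=" by ",
                         constraint=ConstraintSpec.resource(TRANSPORT_CLASS)),
            PositionSpec(role_label="DEPARTURE_LOCATION", required=False,
                         preposition_text=" from ",
                         constraint=ConstraintSpec.resource(LOCATION_CLASS)),
            PositionSpec(role_label="DESTINATION_LOCATION",
                         preposition_text=" to ",
                         constraint=ConstraintSpec.resource(LOCATION_CLASS)),
            PositionSpec(role_label="VIA", required=False,
                         preposition_text=" via ", max_values=None,
                         constraint=ConstraintSpec.resource(LOCATION_CLASS)),
            PositionSpec(role_label="DATETIME", required=False,
                         preposition_text=" on the ",
                         constraint=ConstraintSpec.literal("date")),
        ])


def meet_schema() -> StatementTypeSchema:
    """'PERSON met PERSON_2 on DATE' — a ternary relation with exactly two
    object positions."""
    return define_statement_type(
        label="meets",
        verb_display="met",
        description="two persons meeting on a date",
        examples=["Sarah met Bob on 4th of July 2021"],
        subject_spec=PositionSpec(
            role_label="PERSON", placeholder_text="person",
            constraint=ConstraintSpec.resource(PERSON_CLASS),
            max_values=None),
        object_specs=[
            PositionSpec(role_label="PERSON_2", preposition_text=" ",
                         placeholder_text="met person", max_values=None,
                         constraint=ConstraintSpec.resource(PERSON_CLASS)),
            PositionSpec(role_label="DATE", preposition_text=" on ",
                         placeholder_text="date",
                         constraint=ConstraintSpec.literal("date")),
        ])


# ---------------------------------------------------------------------------
# corpus
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FixtureStatement:
    name: str
    schema_key: str
    record: StatementRecord


@dataclass
class FixtureCorpus:
    seed: int
    n_per_type: int
    schemas: Dict[str, StatementTypeSchema]
    statements: List[FixtureStatement]

    def registry(self) -> SchemaRegistry:
        return SchemaRegistry(self.schemas.values())

    def schema_for(self, stmt: FixtureStatement) -> StatementTypeSchema:
        return self.schemas[stmt.schema_key]

    def statement(self, name: str) -> FixtureStatement:
        for s in self.statements:
            if s.name == name:
                return s
        raise KeyError(name)

    def ontology_graph(self) -> Graph:
        """Class labels and the subclass assertions the constraint checks
        rely on (no reasoner: hierarchy is asserted data)."""
        g = Graph()
        for iri, label in _CLASS_LABELS.items():
            g.add((URIRef(iri), RDFS.label, Literal(label)))
        for sub, sup in _SUBCLASSES.items():
            g.add((URIRef(sub), RDFS.subClassOf, URIRef(sup)))
        return g

    def to_text(self) -> str:
        """Deterministic serialisation of the whole corpus (schemas as
        JSON, statements as canonical triples)."""
        import json
        from .schema_io import schema_to_dict
        parts = []
        for key in sorted(self.schemas):
            parts.append(f"# schema {key}\n" + json.dumps(
                schema_to_dict(self.schemas[key]), indent=2,
                ensure_ascii=False))
        for stmt in self.statements:
            g = to_light_graph(stmt.record, self.schema_for(stmt))
            parts.append(f"# statement {stmt.name}\n" + canonical_turtle(g))
        return "\n".join(parts) + "\n"

    def write_dir(self, path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        from .schema_io import save_schema
        for key, schema in self.schemas.items():
            save_schema(schema, path / f"{key}.json")
        for stmt in self.statements:
            g = to_light_graph(stmt.record, self.schema_for(stmt))
            (path / f"{stmt.name}.ttl").write_text(
                canonical_turtle(g), encoding="utf-8")
        (path / "ontology.ttl").write_text(
            canonical_turtle(self.ontology_graph()), encoding="utf-8")


def _meta(creator: str, when: str) -> ProvenanceMetadata:
    return ProvenanceMetadata(creator=creator, created_at=when)


def make_fixtures(seed: int = 0, n_per_type: int = 0) -> FixtureCorpus:
    """Build the packaged corpus: worked-example statements plus
    ``n_per_type`` seeded synthetic statements per type.  Same inputs,
    byte-identical corpus."""
    if n_per_type < 0:
        raise ValueError("n_per_type must be >= 0")
    minter = IriMinter(base=EX, seed=seed)
    schemas = {
        "measurement": measurement_schema(),
        "measurement_ci": measurement_ci_schema(),
        "travel": travel_schema(),
        "meet": meet_schema(),
    }
    stmts: List[FixtureStatement] = []

    apple1 = ValueBinding.resource(EX + "entity/apple-1", "apple",
                                   resource_class=APPLE_CLASS)
    apple2 = ValueBinding.resource(EX + "entity/apple-2", "apple",
                                   resource_class=APPLE_CLASS)
    orange1 = ValueBinding.resource(EX + "entity/orange-1", "orange",
                                    resource_class=ORANGE_CLASS)
    gram = ValueBinding.resource(GRAM, "grams")
    weight = ValueBinding.resource(WEIGHT, "weight")

    stmts.append(FixtureStatement("basic_apple", "measurement", create_statement(
        schemas["measurement"], apple1,
        {"VALUE": ValueBinding.literal("241.68", "float"), "UNIT": gram},
        _meta("curator-1", "2023-05-01T10:00:00"), minter=minter)))

    def ci_record(subject, main, lower, upper, name, when):
        bindings = {
            "QUALITY": weight,
            "MAIN_VALUE": ValueBinding.literal(main, "float"),
            "UNIT": gram,
        }
        if lower is not None:
            bindings.update({
                "INTERVAL_VALUE": ValueBinding.literal("95", "decimal"),
                "LOWER_VALUE": ValueBinding.literal(lower, "float"),
                "UPPER_VALUE": ValueBinding.literal(upper, "float"),
            })
        return FixtureStatement(name, "measurement_ci", create_statement(
            schemas["measurement_ci"], subject, bindings,
            _meta("curator-1", when), minter=minter))

    stmts.append(ci_record(apple1, "241.68", "241.31", "242.05",
                           "ci_apple", "2023-05-01T10:05:00"))
    stmts.append(ci_record(apple2, "212.45", "212.44", "212.47",
                           "ci_apple_2", "2023-05-01T10:10:00"))
    stmts.append(ci_record(orange1, "165.30", None, None,
                           "orange_no_ci", "2023-05-01T10:15:00"))

    anna = ValueBinding.resource(EX + "entity/anna", "Anna")
    bob = ValueBinding.resource(EX + "entity/bob", "Bob")
    sarah = ValueBinding.resource(EX + "entity/sarah", "Sarah")
    train = ValueBinding.resource(TRAIN, "train")
    berlin = ValueBinding.resource(BERLIN, "Berlin")
    paris = ValueBinding.resource(PARIS, "Paris")
    date_2023 = ValueBinding.literal("2023-04-21", "date",
                                     display_text="21st of April 2023")

    stmts.append(FixtureStatement("travel_anna", "travel", create_statement(
        schemas["travel"], anna,
        {"TRANSPORTATION": train, "DEPARTURE_LOCATION": berlin,
         "DESTINATION_LOCATION": paris, "DATETIME": date_2023},
        _meta("curator-2", "2023-05-02T09:00:00"), minter=minter)))

    via = [ValueBinding.resource(WD + "Q2861", "Osnabrück"),
           ValueBinding.resource(WD + "Q9915", "Hengelo"),
           ValueBinding.resource(WD + "Q803", "Utrecht"),
           ValueBinding.resource(WD + "Q34370", "Rotterdam")]
    stmts.append(FixtureStatement("travel_via", "travel", create_statement(
        schemas["travel"], [anna, bob],
        {"TRANSPORTATION": train, "DEPARTURE_LOCATION": berlin,
         "DESTINATION_LOCATION": paris, "VIA": via, "DATETIME": date_2023},
        _meta("curator-2", "2023-05-02T09:05:00"), minter=minter)))

    stmts.append(FixtureStatement("meet_sarah", "meet", create_statement(
        schemas["meet"], sarah,
        {"PERSON_2": bob,
         "DATE": ValueBinding.literal("2021-07-04", "date",
                                      display_text="4th of July 2021")},
        _meta("curator-2", "2023-05-02T09:10:00"), minter=minter)))

    rng = Random(seed)
    stmts.extend(_synthetic(schemas, rng, minter, n_per_type))
    return FixtureCorpus(seed=seed, n_per_type=n_per_type, schemas=schemas,
                         statements=stmts)


_FIRST_NAMES = ["Ada", "Ben", "Clara", "Dmitri", "Eva", "Farid", "Grete",
                "Hiro", "Ines", "Jonas"]
_CITIES = [("Q64", "Berlin"), ("Q90", "Paris"), ("Q803", "Utrecht"),
           ("Q34370", "Rotterdam"), ("Q2861", "Osnabrück"),
           ("Q1055", "Hamburg"), ("Q1726", "Munich"), ("Q239", "Brussels")]
_TRANSPORT = [("Q870", "train"), ("Q11442", "bicycle"), ("Q1420", "car"),
              ("Q197", "aircraft")]
_QUALITIES = [("Q476572", "weight"), ("Q36253", "length"),
              ("Q11466", "temperature")]
_UNITS = [("Q41803", "gram"), ("Q11570", "kilogram"), ("Q174728", "centimetre"),
          ("Q25267", "degree Celsius")]


def _synthetic(schemas, rng: Random, minter: IriMinter,
               n_per_type: int) -> List[FixtureStatement]:
    out: List[FixtureStatement] = []
    when = "2024-01-01T00:00:00"

    def fruit(i):
        cls, label = rng.choice(
            [(APPLE_CLASS, "apple"), (ORANGE_CLASS, "orange")])
        return ValueBinding.resource(f"{EX}entity/fruit-{i}", label,
                                     resource_class=cls)

    def person(i):
        name = rng.choice(_FIRST_NAMES)
        return ValueBinding.resource(f"{EX}entity/person-{i}", name)

    def pick(pool):
        q, label = rng.choice(pool)
        return ValueBinding.resource(WD + q, label)

    def a_date():
        return ValueBinding.literal(
            f"{rng.randint(2019, 2024)}-{rng.randint(1, 12):02d}-"
            f"{rng.randint(1, 28):02d}", "date")

    for i in range(n_per_type):
        creator = f"user-{rng.randint(1, 5)}"
        value = round(rng.uniform(50, 500), 2)
        out.append(FixtureStatement(f"gen_measurement_{i}", "measurement",
            create_statement(
                schemas["measurement"], fruit(f"m{i}"),
                {"VALUE": ValueBinding.literal(f"{value:.2f}", "float"),
                 "UNIT": pick(_UNITS[:2])},
                _meta(creator, when), minter=minter)))

        main = round(rng.uniform(50, 500), 2)
        delta = round(rng.uniform(0.05, 5.0), 2)
        bindings = {
            "QUALITY": pick(_QUALITIES),
            "MAIN_VALUE": ValueBinding.literal(f"{main:.2f}", "float"),
            "UNIT": pick(_UNITS),
        }
        if rng.random() < 0.6:
            bindings.update({
                "INTERVAL_VALUE": ValueBinding.literal(
                    str(rng.choice([90, 95, 99])), "decimal"),
                "LOWER_VALUE": ValueBinding.literal(
                    f"{main - delta:.2f}", "float"),
                "UPPER_VALUE": ValueBinding.literal(
                    f"{main + delta:.2f}", "float"),
            })
        out.append(FixtureStatement(f"gen_measurement_ci_{i}",
            "measurement_ci", create_statement(
                schemas["measurement_ci"], fruit(f"c{i}"), bindings,
                _meta(creator, when), minter=minter,
                certainty=round(rng.uniform(0.5, 1.0), 2)
                if rng.random() < 0.5 else None)))

        tb = {"DESTINATION_LOCATION": pick(_CITIES)}
        if rng.random() < 0.8:
            tb["TRANSPORTATION"] = pick(_TRANSPORT)
        if rng.random() < 0.8:
            tb["DEPARTURE_LOCATION"] = pick(_CITIES)
        n_via = rng.randint(0, 3)
        if n_via:
            seen = []
            for q, label in rng.sample(_CITIES, n_via):
                seen.append(ValueBinding.resource(WD + q, label))
            tb["VIA"] = seen
        if rng.random() < 0.7:
            tb["DATETIME"] = a_date()
        out.append(FixtureStatement(f"gen_travel_{i}", "travel",
            create_statement(schemas["travel"], person(f"t{i}"), tb,
                             _meta(creator, when), minter=minter)))

        out.append(FixtureStatement(f"gen_meet_{i}", "meet",
            create_statement(
                schemas["meet"], person(f"ma{i}"),
                {"PERSON_2": person(f"mb{i}"), "DATE": a_date()},
                _meta(creator, when), minter=minter,
                negated=rng.random() < 0.1)))
    return out
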