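import pytest

from rosetta_statements import IriMinter, make_fixtures


@pytest.fixture(scope="session")
def corpus():
    """Worked-example statements plus a small seeded synthetic corpus."""
    return make_fixtures(seed=0, n_per_type=6)


@pytest.fixture(scope="session")
def registry(corpus):
    return corpus.registry()


@pytest.fixture(scope="session")
def ontology(corpus):
    return corpus.ontology_graph()


@pytest.fixture()
def minter():
    return IriMinter(seed=123)
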