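import pytest

from ipanon import (
    CategoricalTaxonomy,
    IntervalTaxonomy,
    RandomSource,
    fixture_trees,
    load_fixture,
)


@pytest.fixture
def table5():
    return load_fixture("table5")


@pytest.fixture
def table5_trees():
    return fixture_trees("table5")


@pytest.fixture
def table1():
    return load_fixture("table1")


@pytest.fixture
def table1_trees():
    return fixture_trees("table1")


@pytest.fixture
def rng():
    return RandomSource(20260926)


@pytest.fixture
def toy_trees():
    """Two tiny dimension trees used for brute-force neighbor enumerations."""
    return {
        "X": IntervalTaxonomy("X", 0, 3, widths=[2]),
        "Y": CategoricalTaxonomy("Y", ["u", "v"], [[["*", ["u", "v"]]]]),
    }


@pytest.fixture
def toy_domains():
    return {"X": ["0", "1", "2", "3"], "Y": ["u", "v"]}
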