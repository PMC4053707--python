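import pytest

from mcferm import datasets, thermo


@pytest.fixture(scope="session")
def species():
    return thermo.load_species()


@pytest.fixture(scope="session")
def reactions(species):
    return thermo.load_reactions(species)


@pytest.fixture(scope="session")
def archaea():
    return datasets.load_archaea_clones()


@pytest.fixture(scope="session")
def bacteria():
    return datasets.load_bacteria_clones()


@pytest.fixture(scope="session")
def guild_map():
    return datasets.load_guild_map()


@pytest.fixture(scope="session")
def cstr_yield_tables():
    return datasets.load_cstr_yield_tables()
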