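import pytest

from ribovar import fixtures as fx


@pytest.fixture(scope="session")
def table1_fixtures():
    return {s: fx.load_table1(s) for s in fx.SPECIMENS}


@pytest.fixture(scope="session")
def reconstructed(table1_fixtures):
    return {
        s: fx.reconstruct_alignment(t1) for s, t1 in table1_fixtures.items()
    }


@pytest.fixture(scope="session")
def table2_fixtures():
    return {s: fx.load_table2_fixture(s) for s in fx.SPECIMENS}
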