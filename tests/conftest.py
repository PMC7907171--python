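import numpy as np
import pytest

from evoequiv import fixtures


@pytest.fixture(scope="session")
def closed_world():
    return fixtures.reference_labyrinths()[0]


@pytest.fixture(scope="session")
def open_world():
    return fixtures.reference_labyrinths()[1]


@pytest.fixture(scope="session")
def printed():
    sol1, sol2, sol3 = fixtures.printed_solutions()
    return {"Sol1": sol1, "Sol2": sol2, "Sol3": sol3}


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
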