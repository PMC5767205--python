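import numpy as np
import pytest

from fepnet import load_fixture
from fepnet.network import PerturbationNetwork


@pytest.fixture(scope="session")
def table1():
    return load_fixture("table1")


@pytest.fixture(scope="session")
def table2():
    return load_fixture("table2")


@pytest.fixture(scope="session")
def table3():
    return load_fixture("table3")


@pytest.fixture(scope="session")
def fep_network(table2):
    return PerturbationNetwork.from_table(table2)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
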