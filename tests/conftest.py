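import numpy as np
import pytest

from rpfold.contacts import compute_contact_map
from rpfold.sbm import build_topology
from rpfold.toys import balanced_toy, bulky_core_toy, hairpin_toy, helix_toy


@pytest.fixture(scope="session")
def hairpin():
    return hairpin_toy(seed=0)


@pytest.fixture(scope="session")
def helix10():
    return helix_toy(seed=0, length=10)


@pytest.fixture(scope="session")
def hairpin_map(hairpin):
    return compute_contact_map(hairpin)


@pytest.fixture(scope="session")
def hairpin_topology(hairpin, hairpin_map):
    return build_topology(hairpin, hairpin_map)


@pytest.fixture(scope="session")
def balanced():
    return balanced_toy(seed=0)


@pytest.fixture(scope="session")
def bulky():
    return bulky_core_toy(seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
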