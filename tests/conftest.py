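import pytest

from rangeabc.landscape import least_cost_distance
from rangeabc.synthetic import PriorSpec, constant_deme_record, load_fixture


@pytest.fixture(scope="session")
def mini_world():
    return load_fixture("schematic-old-world-mini")


@pytest.fixture(scope="session")
def small_world():
    return load_fixture("schematic-old-world-small")


@pytest.fixture(scope="session")
def strip16():
    return load_fixture("strip-16")


@pytest.fixture(scope="session")
def island_pair():
    return load_fixture("island-pair")


@pytest.fixture(scope="session")
def mini_priors():
    return PriorSpec.load("priors_mini")


@pytest.fixture(scope="session")
def study_priors():
    return PriorSpec.load("priors")


@pytest.fixture(scope="session")
def mini_distances(mini_world):
    return {
        r: least_cost_distance(mini_world, routing=r)
        for r in ("levant_only", "levant_horn_gibraltar")
    }


@pytest.fixture()
def make_single_deme_record():
    return constant_deme_record
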