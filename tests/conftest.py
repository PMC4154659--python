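import numpy as np
import pytest

from nichesim import HSCParameters, HSCSystem, NicheGrouping, build_transition_table


@pytest.fixture(scope="session")
def params():
    return HSCParameters()


@pytest.fixture(scope="session")
def table(params):
    return build_transition_table(params)


@pytest.fixture()
def single_lineage_system(params):
    return HSCSystem(params, NicheGrouping(1, 1))


@pytest.fixture()
def rng():
    return np.random.Generator(np.random.PCG64(12345))
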