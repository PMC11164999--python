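import numpy as np
import pytest

from scsolu.co2_properties import co2_state
from scsolu.solubility_data import lumiracoxib_table, nimesulide_table


@pytest.fixture(scope="session")
def lumi_table():
    return lumiracoxib_table()


@pytest.fixture(scope="session")
def lumi_states(lumi_table):
    return [co2_state(r.T, r.P) for r in lumi_table]


@pytest.fixture(scope="session")
def nime_table():
    return nimesulide_table()


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240610)
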