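import numpy as np
import pytest

import catcart as cc


@pytest.fixture(scope="session")
def instruments():
    return cc.default_instruments()


@pytest.fixture(scope="session")
def gad7(instruments):
    return instruments["GAD-7"]


@pytest.fixture(scope="session")
def gad7_bank(gad7):
    return cc.generate_item_bank(gad7, cc.SimulationConfig(seed=42), seed=42)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
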