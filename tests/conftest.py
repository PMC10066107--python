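import numpy as np
import pytest

from convopk.presets import load_presets


@pytest.fixture(scope="session")
def presets():
    return load_presets()


@pytest.fixture(scope="session")
def pp3m(presets):
    return presets["PP3M"]


@pytest.fixture(scope="session")
def pp1m(presets):
    return presets["PP1M"]


@pytest.fixture(scope="session")
def er(presets):
    return presets["ER"]


@pytest.fixture(scope="session")
def pp12m(presets):
    return presets["PP12M"]


@pytest.fixture()
def rng():
    return np.random.default_rng(20240915)
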