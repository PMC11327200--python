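import numpy as np
import pytest

from izhmass.presets import case1_preset, case2_preset


@pytest.fixture(scope="session")
def case1():
    return case1_preset()


@pytest.fixture(scope="session")
def case2():
    return case2_preset()


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
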