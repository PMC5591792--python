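import numpy as np
import pytest

from spindlesep.synth import make_montage


@pytest.fixture(scope="session")
def montage58():
    return make_montage(58, "standard_1020_58")


@pytest.fixture(scope="session")
def montage16():
    return make_montage(16, "fibonacci_sphere")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
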