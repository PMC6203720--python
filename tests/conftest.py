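import numpy as np
import pytest

from gelcav import nominal_properties
from gelcav.synthetic import make_pulse


@pytest.fixture(scope="session")
def gel():
    return nominal_properties("paper_nominal_gel")


@pytest.fixture(scope="session")
def water():
    return nominal_properties("water")


@pytest.fixture(scope="session")
def collagen():
    return nominal_properties("collagen_like")


@pytest.fixture(scope="session")
def pulse500():
    """Default raised-cosine impact pulse, 500 g amplitude metadata."""
    return make_pulse(500.0)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20231115)
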