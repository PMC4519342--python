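import numpy as np
import pytest

from bemeta import constants as c
from bemeta import synthetic


@pytest.fixture(scope="session")
def helix37():
    return synthetic.build_ideal_structure("alpha_helix", 37)


@pytest.fixture(scope="session")
def hairpin16():
    return synthetic.build_ideal_structure("beta_hairpin", 16)


@pytest.fixture(scope="session")
def kT():
    return c.kT()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
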