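import numpy as np
import pytest

from lbagrid.phylo_core import lg, poisson


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def poisson_model():
    return poisson()


@pytest.fixture(scope="session")
def lg_model():
    return lg()
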