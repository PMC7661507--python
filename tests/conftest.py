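import numpy as np
import pytest

from polyion.equilibria import GLOBAL_FIT_RATES, RateSet


@pytest.fixture(scope="session")
def rates() -> RateSet:
    """Globally fitted rate coefficients of the P/H binding scheme."""
    return GLOBAL_FIT_RATES


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
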