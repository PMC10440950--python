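import numpy as np
import pytest

from fraclag.model import (FractionalOrders, default_initial_state,
                           default_parameters)


@pytest.fixture(scope="session")
def params():
    return default_parameters()


@pytest.fixture(scope="session")
def init_state():
    return default_initial_state()


@pytest.fixture(scope="session")
def classical_orders():
    return FractionalOrders.uniform(1.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
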