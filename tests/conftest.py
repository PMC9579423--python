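import numpy as np
import pytest

import vartime as vt
from vartime import presets


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def low_order_sessions():
    """Ten 1,000-trial closed-loop sessions from the order-1 reference vARNN."""
    truth = presets.low_order_varnn_params()
    return vt.simulate_sessions(vt.VARNNSampler(truth), 10, 1000, seed=0)


@pytest.fixture(scope="session")
def arnn_sessions():
    """Matched reward-blind (additive-noise-only) control sessions."""
    truth = presets.low_order_arnn_params()
    return vt.simulate_sessions(vt.VARNNSampler(truth), 10, 1000, seed=0)
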