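import numpy as np
import pytest

from kurastim._utils import TWO_PI
from kurastim.network_model import NetworkParams, simulate


@pytest.fixture(scope="session", autouse=True)
def warm_kernel():
    """Trigger numba compilation once so individual tests time cleanly."""
    p = NetworkParams(omega0=TWO_PI * 30, gamma=TWO_PI, K=1.0, D=0.1, N=8)
    simulate(p, duration=0.01, dt=5e-4, seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def beta_params():
    """A partially synchronised beta-band network used by several tests."""
    gamma = TWO_PI * 1.0
    return NetworkParams(omega0=TWO_PI * 27, gamma=gamma, K=4 * gamma, D=1.0, N=200)
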