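import numpy as np
import pytest

from mpdc.network import MPDCNet, NetworkConfig


@pytest.fixture(scope="session")
def tiny_fixtures():
    from mpdc.synthetic import tiny_tensor_fixtures
    return tiny_tensor_fixtures()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="module")
def small_net():
    """Depth-2, width-4 three-branch network on 8x8 inputs (fast forward/backward)."""
    return MPDCNet(NetworkConfig(base_width=4, depth=2), rng_seed=0)


def finite_difference_grad(f, x, eps=1e-3):
    """Central finite differences of a scalar function of an array."""
    g = np.zeros_like(x, dtype=np.float64)
    it = np.nditer(x, flags=["multi_index"])
    for _ in it:
        i = it.multi_index
        xp = x.copy()
        xp[i] += eps
        xm = x.copy()
        xm[i] -= eps
        g[i] = (f(xp) - f(xm)) / (2 * eps)
    return g
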