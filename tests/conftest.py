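import numpy as np
import pytest
from hypothesis import settings

# deterministic hypothesis runs
settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def rayleigh_jumps(rng, d_um2_s, lag_s, n):
    """Exact 2D Brownian jump magnitudes: r^2 ~ Exponential(4 D dt)."""
    return np.sqrt(rng.exponential(4.0 * d_um2_s * lag_s, size=n))


@pytest.fixture
def jump_sampler():
    return rayleigh_jumps
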