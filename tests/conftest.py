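import numpy as np
import pytest

from lamsal import synthetic as syn


@pytest.fixture(scope="session")
def default_timeline():
    """The standard run: 6 x 30-s blocks + 15-s fixation, 60 events/block."""
    return syn.generate_block_design(seed=1)


@pytest.fixture(scope="session")
def v1_phantom():
    return syn.generate_laminar_phantom(200, "v1_like", 1.0, 50.0, seed=3)


@pytest.fixture(scope="session")
def quiet_phantom():
    """Noiseless, driftless v1-like phantom for exact-recovery checks."""
    return syn.generate_laminar_phantom(200, "v1_like", 1.0, 50.0, seed=3,
                                        noise_sd=0.0, drift_amplitude=0.0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
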