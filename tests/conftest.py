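import numpy as np
import pytest

from psinet import SimConfig, sweep_density, sweep_homophily


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def density_sweep():
    """Full no-homophily density sweep: 16 r values x 50 replicates, n=50."""
    return sweep_density(SimConfig(n=50, seed=1))


@pytest.fixture(scope="session")
def homophily_sweep():
    """Homophily sweep at fixed r=0.9: 9 H values x 50 replicates, n=50."""
    return sweep_homophily(SimConfig(n=50, seed=2, mode="homophily", r=0.9))
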