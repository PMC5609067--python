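import pytest

from pcwdn.network import load_network, mannan_fixture_tables
from pcwdn.simulate import SimulationConfig, simulate_bundle


@pytest.fixture(scope="session")
def mannan_net():
    """Three-reaction mannan pathway fixture (one orphan transport step)."""
    return load_network(*mannan_fixture_tables())


@pytest.fixture(scope="session")
def small_cfg():
    """Compact simulation config used by most integration tests."""
    return SimulationConfig(n_genes=300, n_network_genes=60)


@pytest.fixture(scope="session")
def small_bundle(small_cfg):
    return simulate_bundle(small_cfg, seed=7)
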