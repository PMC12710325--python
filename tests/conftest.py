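import pytest

from abyssalgv import (SimulationConfig, simulate_asv_table, simulate_bins,
                       simulate_depth_abundance, simulate_lineages)


@pytest.fixture(scope="session")
def config():
    """Default simulation design with a fixed seed."""
    return SimulationConfig(seed=1)


@pytest.fixture(scope="session")
def depth_data(config):
    return simulate_depth_abundance(config)


@pytest.fixture(scope="session")
def bin_data(config):
    return simulate_bins(config)


@pytest.fixture(scope="session")
def lineage_data(config):
    return simulate_lineages(config)


@pytest.fixture(scope="session")
def asv_data(config):
    return simulate_asv_table(config)
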