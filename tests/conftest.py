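import pytest

from xconcord import SimulationConfig, published_counts_fixture, simulate


@pytest.fixture(scope="session")
def fixture_tables():
    """The deterministic 2749-gene published-counts fixture."""
    return published_counts_fixture()


@pytest.fixture(scope="session")
def small_dataset():
    """A small simulated dataset shared across tests (fixed seed)."""
    return simulate(SimulationConfig(n_genes=300, depth=30_000, seed=11))
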