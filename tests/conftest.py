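import pytest

from fluxrestore.pipeline import run_pipeline
from fluxrestore.synthetic_data import (default_medium, generate_toy_network,
                                        simulate_proteome)


@pytest.fixture(scope="session")
def toy_network():
    return generate_toy_network()


@pytest.fixture(scope="session")
def medium():
    return default_medium()


@pytest.fixture(scope="session")
def proteome_truth(toy_network):
    return simulate_proteome(toy_network, seed=1)


@pytest.fixture(scope="session")
def study(toy_network):
    """One full pipeline run (simulation seed 1), shared across tests."""
    return run_pipeline(seed=1)
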