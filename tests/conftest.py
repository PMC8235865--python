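import numpy as np
import pytest

from evechain.datasets import load_aaegl5_eve_table
from evechain.simulate import SimulationConfig, simulate_genomes, simulate_integration


@pytest.fixture(scope="session")
def aaegl5_records():
    """The 29 curated AaegL5 EVE fragments."""
    return load_aaegl5_eve_table()


@pytest.fixture(scope="session")
def aaegl5_by_id(aaegl5_records):
    return {r.identifier: r for r in aaegl5_records}


@pytest.fixture(scope="session")
def small_simulation():
    """One modest simulated integration scenario shared across tests."""
    config = SimulationConfig(seed=7, n_events=3, host_len=500_000,
                              min_event_separation=80_000, n_samples=12)
    rng = np.random.default_rng(config.seed)
    host, virus = simulate_genomes(config, rng)
    modified, truth = simulate_integration(host, virus, config, rng)
    return config, host, virus, modified, truth
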