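import numpy as np
import pytest

from coevoseq import (
    DeletionWindow,
    LengthBins,
    PARASITE_ALPHA,
    PARASITE_GAMMA,
    ReferenceSet,
    SimulationConfig,
    generate_reference_set,
    simulate_serial_transfer,
)

pytest_plugins = []


@pytest.fixture(scope="session")
def refs() -> ReferenceSet:
    """Small reference set: 120 nt host with two nested parasite windows."""
    windows = {
        PARASITE_ALPHA: DeletionWindow(21, 100),  # product 40 nt
        PARASITE_GAMMA: DeletionWindow(41, 90),   # product 70 nt
    }
    return generate_reference_set(120, windows, seed=7)


@pytest.fixture(scope="session")
def small_bins() -> LengthBins:
    return LengthBins(
        (
            (PARASITE_ALPHA, 30, 50),
            (PARASITE_GAMMA, 60, 80),
            ("host", 110, 130),
        )
    )


@pytest.fixture(scope="session")
def small_sim(refs):
    """A short stochastic serial-transfer run shared across tests."""
    cfg = SimulationConfig(
        n_rounds=4,
        host_length=refs.host_length,
        deletion_windows=dict(refs.windows),
        substitution_rate=1e-3,
        indel_rate=1e-4,
        deletion_event_rate=5e-3,
        initial_population=1500,
        droplet_cap=300,
        length_advantage_exponent=0.5,
        reads_per_round=300,
        seq_error_rate=0.0,
        seed=11,
    )
    populations, truth = simulate_serial_transfer(cfg, refs)
    return cfg, populations, truth


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
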