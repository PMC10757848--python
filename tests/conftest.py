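import numpy as np
import pandas as pd
import pytest

from milkres.simulate import SimulationConfig, simulate_herd


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(n_base_animals=40, n_cows=120, seed=11)


@pytest.fixture(scope="session")
def small_herd(small_config):
    """One modest simulated herd shared across read-only tests."""
    return simulate_herd(small_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


def constant_cow(animal_id=1, yield_kg=10.0, n=12, interval=14):
    dims = np.arange(1, n * interval, interval)[:n]
    return pd.DataFrame(
        {"animal_id": animal_id, "dim": dims, "yield_kg": float(yield_kg)}
    )
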