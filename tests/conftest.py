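import numpy as np
import pytest

from flocknoise import SimulationConfig, simulate_flock


@pytest.fixture(scope="session")
def short_config():
    """A short flight configuration for fast structural tests."""
    return SimulationConfig(n_steps=256, seed=42)


@pytest.fixture(scope="session")
def short_flight(short_config):
    return simulate_flock(short_config)


def lag_autocorr(x: np.ndarray, lag: int) -> float:
    """Sample autocorrelation at a given lag (helper shared by tests)."""
    x = np.asarray(x, dtype=float)
    x = x - x.mean()
    return float(np.dot(x[:-lag], x[lag:]) / np.dot(x, x))
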