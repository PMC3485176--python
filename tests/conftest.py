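import numpy as np
import pytest

from ecosim import IntegratorConfig, Parameters, initial_state


@pytest.fixture(scope="session")
def params() -> Parameters:
    return Parameters()


@pytest.fixture()
def coculture_state() -> np.ndarray:
    return initial_state(c1=5e4, c2=5e4)


@pytest.fixture()
def short_config() -> IntegratorConfig:
    return IntegratorConfig(t_end=5.0, dt=0.005, record_every=10, seed=7)


def random_states(n: int, seed: int = 0) -> np.ndarray:
    """Nonnegative random states spanning the magnitudes the model visits."""
    rng = np.random.default_rng(seed)
    scales = np.array([1e9, 1e9, 1e4, 1e4, 1e3, 1e3, 1e3, 1e5, 1e5])
    states = rng.uniform(size=(n, 9)) * scales
    states[rng.uniform(size=(n, 9)) < 0.2] = 0.0  # exercise zero corners
    return states
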