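import numpy as np
import pytest

from glvident import (
    GLVParameters,
    NoiseModel,
    benchmark_initial_state,
    benchmark_parameters,
)


@pytest.fixture(scope="session")
def value1_params() -> GLVParameters:
    return benchmark_parameters(1)


@pytest.fixture(scope="session")
def value2_params() -> GLVParameters:
    return benchmark_parameters(2)


@pytest.fixture(scope="session")
def value1_x0() -> np.ndarray:
    return benchmark_initial_state(1)


@pytest.fixture(scope="session")
def value2_x0() -> np.ndarray:
    return benchmark_initial_state(2)


@pytest.fixture(scope="session")
def short_times() -> np.ndarray:
    return np.linspace(0.0, 2.0, 21)


@pytest.fixture()
def noiseless() -> NoiseModel:
    return NoiseModel(sigma=np.zeros(3), dt=0.001, V=500, seed=0)


def random_stable_system(n: int, seed: int) -> tuple[GLVParameters, np.ndarray]:
    """A random n-species system with self-limitation strong enough to keep
    the dynamics bounded on [0, 5] (used by the numeric invariance checks)."""
    rng = np.random.default_rng(seed)
    r = rng.uniform(0.5, 3.0, size=n)
    B = rng.uniform(-0.2, 0.2, size=(n, n))
    np.fill_diagonal(B, -rng.uniform(0.5, 1.5, size=n))
    x0 = rng.uniform(0.5, 3.0, size=n)
    return GLVParameters(r, B), x0
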