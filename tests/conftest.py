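import numpy as np
import pytest

from meiosim import ParameterSet, default_parameters, wild_type


@pytest.fixture(scope="session")
def params() -> ParameterSet:
    return default_parameters()


@pytest.fixture(scope="session")
def wt():
    return wild_type()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260927)


def random_admissible_states(rng: np.random.Generator, n: int) -> np.ndarray:
    """Random states in the admissible box [0,1]^3 x [0, hi]^3."""
    pools = rng.uniform(0.0, 1.0, size=(n, 3))
    levels = rng.uniform(0.0, 3.0, size=(n, 3))
    return np.hstack([pools, levels])
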