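import numpy as np
import pytest

from dtimf import generate_synthetic_dataset


@pytest.fixture(scope="session")
def planted_dataset():
    """The planted low-rank benchmark used throughout: 60 drugs x 40 targets,
    rank 4, 10% interaction density."""
    return generate_synthetic_dataset(n=60, m=40, k_true=4, density=0.1, seed=1)


@pytest.fixture(scope="session")
def small_dataset():
    """A quick noise-free instance for per-engine unit tests."""
    return generate_synthetic_dataset(n=20, m=15, k_true=3, density=0.15, noise=0.0, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
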