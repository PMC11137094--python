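import numpy as np
import pytest

from divstages import GrowthLaw, generate_benchmark_suite


@pytest.fixture(scope="session")
def growth() -> GrowthLaw:
    """Default growth law: mu = ln 2, time in doubling units."""
    return GrowthLaw()


@pytest.fixture(scope="session")
def benchmark_suite_seed0():
    """One benchmark suite shared across tests (seed 0, n = 5000 per condition)."""
    return generate_benchmark_suite(seed=0, n_cycles=5000)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
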