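import numpy as np
import pytest

from cemda import MDADataset, generate_planted_benchmark


@pytest.fixture(scope="session")
def benchmark():
    """Default planted benchmark shared (read-only) across tests."""
    return generate_planted_benchmark(seed=1)


@pytest.fixture(scope="session")
def tiny_dataset():
    """A 6-miRNA x 5-disease dataset small enough for smoke training."""
    bench = generate_planted_benchmark(
        m=6, n=5, n_blocks=2, p_in=0.8, p_out=0.1, noise=0.0, seed=3,
        dag_depth=2)
    return bench.dataset


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
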