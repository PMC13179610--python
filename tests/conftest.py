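import numpy as np
import pytest

from regprobe import ProbingInstance, generate_instance, counterexample_fixture


@pytest.fixture(scope="session")
def counterexample():
    return counterexample_fixture()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_network_instance():
    """A z=1 Network-setting instance shared across read-only tests."""
    return generate_instance("network", 1, np.random.default_rng(7))


def random_small_instance(rng, n_a=4, n_b=3, vmax=2):
    """Random small pmf-backed instance for exhaustive checks."""
    raw = rng.random((n_a, n_b, vmax + 1))
    return ProbingInstance.from_pmfs(raw / raw.sum(axis=2, keepdims=True))
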