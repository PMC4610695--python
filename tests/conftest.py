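import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20151019)


def random_instance(rng, n=None, k=None):
    """A random non-degenerate (phenotypes, genotypes) pair."""
    k = k if k is not None else int(rng.choice([1, 2, 5, 10]))
    # keep n comfortably above K so the phenotype covariance is invertible
    n = n if n is not None else int(rng.integers(max(10, 4 * k), 501))
    while True:
        g = rng.binomial(2, rng.uniform(0.1, 0.5), size=n)
        if np.unique(g).size >= 2:
            break
    y = rng.standard_normal((n, k))
    return y, g


@pytest.fixture
def make_instance(rng):
    def _make(n=None, k=None):
        return random_instance(rng, n=n, k=k)
    return _make
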