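import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(987654321)


def random_symmetric_phi(rng: np.random.Generator, k: int) -> np.ndarray:
    """A strictly positive symmetric point on the K^2 simplex."""
    m = rng.dirichlet(np.ones(k * k)).reshape(k, k) + 0.01
    m = 0.5 * (m + m.T)
    return m / m.sum()


def random_gl_triples(rng: np.random.Generator, m: int) -> np.ndarray:
    """Positive GL triples, deliberately unnormalized."""
    return rng.uniform(0.01, 2.0, size=(m, 3))
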