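import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


def random_pvector(rng, n=None, max_n=50):
    """Mixture of uniforms and left-skewed betas, like a DE p-value set."""
    if n is None:
        n = int(rng.integers(1, max_n + 1))
    signal = rng.random(n) < 0.3
    p = np.where(signal, rng.beta(0.2, 5.0, size=n), rng.random(n))
    return np.clip(p, 0.0, 1.0)
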