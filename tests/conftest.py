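import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from mondocons import default_family_spec, simulate_family

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_family():
    """The canonical synthetic family (34 x 1100, seed 11) plus ground truth."""
    return simulate_family(default_family_spec(11))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


def random_counts(rng, max_total=60):
    """A random count vector over the 20 amino acids (at least 1 residue)."""
    k = rng.integers(1, 6)
    counts = np.zeros(20, dtype=np.int64)
    idx = rng.choice(20, size=k, replace=False)
    counts[idx] = rng.integers(1, max_total // k + 1, size=k)
    return counts
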