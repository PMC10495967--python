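import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("default", derandomize=True, deadline=None)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture
def small_regression(rng):
    """Well-conditioned n > p problem with a sparse truth."""
    n, p = 60, 8
    X = rng.standard_normal((n, p))
    beta = np.array([3.0, 0.0, 0.0, -2.0, 0.0, 0.0, 0.0, 1.5])
    y = X @ beta + 0.5 * rng.standard_normal(n)
    return X, y, beta


def random_instances(n_instances=20, seed=1234, max_n=50, max_p=8):
    """Small random regression problems for equivalence-oracle checks."""
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_instances):
        n = int(rng.integers(12, max_n + 1))
        p = int(rng.integers(2, max_p + 1))
        X = rng.standard_normal((n, p))
        beta = np.where(rng.random(p) < 0.5, 0.0, rng.normal(0, 2, p))
        y = X @ beta + rng.standard_normal(n)
        out.append((X, y, beta))
    return out
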