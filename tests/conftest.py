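import numpy as np
import pytest

from permvarsel import Dataset, simulate_m1, simulate_m2


@pytest.fixture(scope="session")
def m1_data() -> Dataset:
    """One study-scale linear sample (n=200, p=15, 5 active covariates)."""
    return simulate_m1(seed=3)


@pytest.fixture(scope="session")
def m2_data() -> Dataset:
    """One study-scale cubic single-index sample."""
    return simulate_m2(seed=3)


@pytest.fixture()
def tiny_data() -> Dataset:
    """Small deterministic sample for exact-arithmetic checks."""
    rng = np.random.default_rng(42)
    X = rng.normal(size=(12, 2))
    y = 1.5 * X[:, 0] - 0.5 * X[:, 1] + rng.normal(scale=0.1, size=12)
    return Dataset(X, y, ("a", "b"))
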