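import numpy as np
import pytest

from ckm import SimSpec, generate, standardize


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture
def easy_data():
    """Well-separated 3-cluster data: 50 signaling + 50 noise columns."""
    ds = generate(SimSpec(K=3, n_per_cluster=50, n_signal=50, V=50,
                          delta_mu=1.0, seed=424242))
    return ds, standardize(ds.x_raw)


@pytest.fixture
def tiny_separated():
    """An 8x4 instance with 2 clusters separated on the first two columns."""
    rng = np.random.default_rng(7)
    X = rng.normal(scale=0.05, size=(8, 4))
    X[:4, :2] += 3.0
    X[4:, :2] -= 3.0
    labels = np.array([1, 1, 1, 1, 2, 2, 2, 2])
    return X - X.mean(axis=0), labels
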