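import numpy as np
import pytest

from maci.datasets_io import DomainDataset, ProblemConfig


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def two_gaussian_domains(rng):
    """A small labeled source + unlabeled target with mild shift."""
    def make(n_per_class=10, d=4, shift=0.3, seed=0):
        r = np.random.default_rng(seed)
        y = np.repeat([1, 2], n_per_class)
        X = r.standard_normal((2 * n_per_class, d))
        X[y == 1, 0] += 3.0
        Xt = r.standard_normal((2 * n_per_class, d)) + shift
        Xt[y == 1, 0] += 3.0
        src = DomainDataset(X, y, name="src")
        tgt = DomainDataset(Xt, name="tgt")
        return src, tgt, y
    return make


@pytest.fixture
def fast_config():
    """Small solver budget for unit tests."""
    return ProblemConfig(max_iter=6, seed=0, k_neighbors=3)
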