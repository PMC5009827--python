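import numpy as np
import pytest

import graphscca as g


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_data(rng):
    """Standardized random paired data, n=30, p=10, q=12."""
    X = rng.standard_normal((30, 10))
    Y = rng.standard_normal((30, 12))
    return g.standardize(g.PairedData(X, Y))


def make_correlated_data(seed: int, n: int = 40, p: int = 12, q: int = 14):
    """Paired data with a genuine shared latent factor (standardized)."""
    rng = np.random.default_rng(seed)
    z = rng.standard_normal(n)
    X = rng.standard_normal((n, p))
    Y = rng.standard_normal((n, q))
    X[:, :4] += np.outer(z, np.full(4, 1.5))
    Y[:, :5] += np.outer(z, np.full(5, 1.5))
    return g.standardize(g.PairedData(X, Y))


def brute_force_goscar(u, edges):
    """Independent pairwise oracle: plain double loop over the edge list."""
    total = 0.0
    for i, j in edges:
        total += max(abs(u[i]), abs(u[j]))
    return total


def brute_force_oscar(u):
    """All-pairs oracle for the complete-graph (OSCAR) case."""
    p = len(u)
    total = 0.0
    for i in range(p):
        for j in range(i + 1, p):
            total += max(abs(u[i]), abs(u[j]))
    return total
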