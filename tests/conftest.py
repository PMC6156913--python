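import numpy as np
import pytest

from towse.residualize import ResidualizedData


def make_resid(rng, n, m, sparse_frac=0.0):
    """Random centred residual-data instance, optionally with sparse columns."""
    y = rng.normal(size=n)
    X = rng.normal(size=(n, m))
    if sparse_frac:
        for j in range(m // 2):
            X[:, j] *= rng.random(n) < sparse_frac
    return ResidualizedData(y_res=y - y.mean(), X_res=X - X.mean(axis=0))


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def worked_n3():
    """The hand-enumerable single-column instance y~ = x~ = (-1, 0, 1)."""
    v = np.array([-1.0, 0.0, 1.0])
    return ResidualizedData(y_res=v.copy(), X_res=v[:, None].copy())
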