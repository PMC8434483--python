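import numpy as np
import pytest

from s2rqsar import DescriptorMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_matrix(values: np.ndarray, names=None, ids=None, provider="test") -> DescriptorMatrix:
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    names = names or [f"X{j}" for j in range(p)]
    ids = ids or [f"m{i}" for i in range(n)]
    return DescriptorMatrix(ids, names, values, provider)


@pytest.fixture
def small_planted(rng):
    """50 x 10 matrix with y = 2*A + 3*B + small noise."""
    X = rng.standard_normal((50, 10))
    names = [chr(ord("A") + j) for j in range(10)]
    y = 2.0 * X[:, 0] + 3.0 * X[:, 1] + 0.05 * rng.standard_normal(50)
    return make_matrix(X, names=names), y
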