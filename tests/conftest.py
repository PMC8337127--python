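import numpy as np
import pytest

from gtskfs import FeatureMatrix, FuzzyRuleBase, map_features


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def two_cloud_data():
    """20 points in two well-separated clouds at (-10, 0) and (+10, 0)."""
    rng = np.random.default_rng(7)
    a = rng.normal(0, 0.5, size=(10, 2)) + np.array([-10.0, 0.0])
    b = rng.normal(0, 0.5, size=(10, 2)) + np.array([10.0, 0.0])
    return np.vstack([a, b])


def random_rule_base(rng, k: int, d: int, width_lo: float = 0.3, width_hi: float = 2.0):
    return FuzzyRuleBase(
        centers=rng.normal(0, 1, size=(k, d)),
        widths=rng.uniform(width_lo, width_hi, size=(k, d)),
    )


def random_instance(rng, n: int, d: int, k: int):
    """Random mapped design + targets for solver tests."""
    rb = random_rule_base(rng, k, d)
    X = rng.normal(0, 1, size=(n, d))
    mapped = map_features(rb, X)
    y = rng.normal(0, 1, size=n)
    return mapped, y, X


@pytest.fixture
def affine_matrix():
    """Noiseless exactly-affine data: y = 0.5 + 2 x1 - 3 x2 + x3."""
    rng = np.random.default_rng(3)
    X = rng.normal(0, 1, size=(60, 3))
    y = 0.5 + X @ np.array([2.0, -3.0, 1.0])
    return FeatureMatrix(X=X, columns=["x1", "x2", "x3"], y=y)
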