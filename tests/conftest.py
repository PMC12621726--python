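import numpy as np
import pytest

from muhmds.geometry import lift


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_sheet_points(rng):
    """30 ambient points on the hyperboloid at moderate radius."""
    spacelike = rng.normal(scale=1.0, size=(30, 3))
    return lift(spacelike)


def random_dissimilarity(rng, n, scale=1.0):
    """Symmetric nonnegative matrix with zero diagonal."""
    a = np.abs(rng.normal(scale=scale, size=(n, n)))
    d = (a + a.T) / 2
    np.fill_diagonal(d, 0.0)
    return d
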