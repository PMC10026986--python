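import numpy as np
import pytest

from svsdg.laguerre import laguerre_basis
from svsdg.series import RRSeries


@pytest.fixture(scope="session")
def basis():
    return laguerre_basis(alpha=0.2, max_order=8, length=500)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def random_rr(rng):
    intervals = 0.8 + 0.05 * rng.standard_normal(200)
    return RRSeries.from_intervals(intervals)


def mad(x):
    x = np.asarray(x, float)
    return float(np.median(np.abs(x - np.median(x))))
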