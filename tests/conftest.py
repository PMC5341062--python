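import numpy as np
import pytest

import freqphase as fp


@pytest.fixture(scope="session")
def grid41():
    """The standard ±40 s lag grid at TR = 2 s (41 points)."""
    return fp.make_lag_grid(2.0, 40.0)


@pytest.fixture(scope="session")
def basis41(grid41):
    """Default Bartlett-windowed basis: 4 cosines + 4 sines on the 41-point grid."""
    return fp.build_basis(grid=grid41)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260929)


def standardized_noise(rng, n=300, tr=2.0):
    ts = fp.TimeSeries(values=rng.standard_normal(n), tr=tr)
    return fp.standardize(ts)


@pytest.fixture()
def std_pair(rng):
    """Two independent standardized noise series of the standard length."""
    return standardized_noise(rng), standardized_noise(rng)
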