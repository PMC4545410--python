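import numpy as np
import pytest

import growthspec as gs


@pytest.fixture
def rng():
    return np.random.default_rng(20250921)


@pytest.fixture
def white_spectrum():
    """Smoothed spectrum of a standardized white-noise series, N=256."""
    vals = np.random.default_rng(7).normal(size=256)
    std = gs.standardize(vals)
    return gs.smooth_density(gs.periodogram(std))
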