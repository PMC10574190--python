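import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_spectra(rng):
    """20 x 100 random spectra with a smooth structure plus noise."""
    wl = np.linspace(1000, 2500, 100)
    base = np.exp(-0.5 * ((wl - 1800) / 200) ** 2)
    X = 1.0 + rng.uniform(0.5, 1.5, (20, 1)) * base + 0.05 * rng.standard_normal((20, 100))
    return wl, X
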