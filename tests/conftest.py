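import numpy as np
import pytest

from bandtree import PowerSpectrum


@pytest.fixture
def make_random_spectrum():
    """Factory for random spectra: sorted jittered frequency grid, positive psd."""

    def _make(seed: int, n: int = 30, fmin: float = 1.0, fmax: float = 30.0) -> PowerSpectrum:
        rng = np.random.default_rng(seed)
        f = np.sort(rng.uniform(fmin, fmax, n))
        f = f + np.arange(n) * 1e-9  # guard against duplicate draws
        psd = rng.uniform(0.05, 5.0, n)
        return PowerSpectrum(f, psd)

    return _make


@pytest.fixture
def step_spectrum():
    """Two-plateau spectrum: psd = e^0 below 10 Hz, e^1 above; log target steps at 10."""
    f = np.arange(1.0, 21.0)
    psd = np.where(f < 10.5, 1.0, np.e)
    return PowerSpectrum(f, psd)
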