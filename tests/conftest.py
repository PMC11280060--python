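import numpy as np
import pytest

from resinate import config
from resinate.specmodel import Spectrum
from resinate.synthdata import default_sample_specs


def lorentzian(axis, center, fwhm_ppm, amplitude=1.0):
    """Peak-normalized Lorentzian (height = amplitude at center)."""
    hw = 0.5 * fwhm_ppm
    return amplitude * hw**2 / ((axis - center) ** 2 + hw**2)


def make_spectrum(centers, amplitudes, fwhm_hz=60.0,
                  axis=(0.0, 200.0, 4096), meta=None):
    """Noiseless multi-line Lorentzian spectrum on an ascending-built axis."""
    lo, hi, n = axis
    x = np.linspace(lo, hi, n)
    fwhm_ppm = fwhm_hz / config.DEFAULT_LARMOR_MHZ
    y = np.zeros_like(x)
    for c, a in zip(centers, amplitudes):
        y += lorentzian(x, c, fwhm_ppm, a)
    return Spectrum(x, y, dict(meta or {}))


@pytest.fixture(scope="session")
def sample_specs():
    return default_sample_specs()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
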