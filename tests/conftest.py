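import numpy as np
import pytest

from aggphot import IRFSpec, Spectrum, SpectrumKind


@pytest.fixture
def irf120() -> IRFSpec:
    """The 120 fs Gaussian instrument response used throughout."""
    return IRFSpec(fwhm_ps=0.12)


@pytest.fixture
def gaussian_spectrum():
    """Factory: noiseless Gaussian band spectrum on a 1 nm grid."""

    def make(center=940.0, sigma=40.0, area=1.0, lo=800.0, hi=1300.0, kind=SpectrumKind.EMISSION):
        wl = np.arange(lo, hi + 0.5)
        amp = area / (sigma * np.sqrt(2 * np.pi))
        y = amp * np.exp(-((wl - center) ** 2) / (2 * sigma**2))
        return Spectrum(wl, y, kind)

    return make
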