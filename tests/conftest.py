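import numpy as np
import pytest

from peatspec.spectra import Spectrum


def make_spectrum(absorbance, lo=650.0, step=2.0, sample_id="fix"):
    a = np.asarray(absorbance, dtype=float)
    w = lo + step * np.arange(a.size)
    return Spectrum(sample_id, w, a)


@pytest.fixture
def triangle_spectrum():
    """Triangular band of height 0.5 over 1000-1060 cm^-1, zero elsewhere.

    On the 2 cm^-1 grid its trapezoidal area is exactly 15 (= 0.5*60*0.5).
    """
    w = np.arange(650.0, 4001.0, 2.0)
    a = np.zeros_like(w)
    band = (w >= 1000) & (w <= 1060)
    a[band] = 0.5 * (1.0 - np.abs(w[band] - 1030.0) / 30.0)
    return Spectrum("triangle", w, a)


@pytest.fixture
def grid():
    return np.arange(650.0, 4001.0, 2.0)
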