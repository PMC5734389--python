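import numpy as np
import pytest

from cdmatch import BasisSpec, Spectrum, Units, generate_spectrum


@pytest.fixture
def helix_spectrum() -> Spectrum:
    """A clean mostly-helical synthetic spectrum on a dense grid."""
    return generate_spectrum(BasisSpec(fractions=(0.8, 0.1, 0.1), seed=7))


@pytest.fixture
def sheet_spectrum() -> Spectrum:
    return generate_spectrum(BasisSpec(fractions=(0.1, 0.8, 0.1), seed=8))


@pytest.fixture
def line_spectrum() -> Spectrum:
    """values = 2*wavelength: linear interpolation reproduces it exactly."""
    wl = np.arange(180.0, 261.0)
    return Spectrum(id="line", wavelengths=wl, values=2.0 * wl)


def brute_nrmsd(query_vals, test_vals) -> float:
    """Independent NRMSD: plain Python loops over the defining formula."""
    num = sum((float(q) - float(t)) ** 2 for q, t in zip(query_vals, test_vals))
    den = sum(float(q) ** 2 for q in query_vals)
    return (num / den) ** 0.5
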