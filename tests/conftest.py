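import numpy as np
import pytest

from maldiscreen import CentroidSpectrum, default_database, parse_formula


@pytest.fixture(scope="session")
def database():
    return default_database()


@pytest.fixture
def tpp():
    return parse_formula("C18H15O4P")


def make_spectrum(peaks, polarity="positive", well_id="W"):
    """Build a CentroidSpectrum from an iterable of (mz, intensity)."""
    peaks = sorted(peaks)
    mz = np.array([p[0] for p in peaks])
    inten = np.array([p[1] for p in peaks])
    return CentroidSpectrum(mz, inten, polarity, well_id)
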