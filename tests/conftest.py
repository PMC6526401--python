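import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from specacc import (
    Formula,
    PeakShapeModel,
    ProfileSpectrum,
    default_calibrants,
    default_table,
)

# The six study analyte ions (ion composition, exact m/z to 4 d.p.)
ANALYTE_IONS = {
    "A": ("C15H23NO3Na+", 288.1570),
    "B": ("C13H20NO+", 206.1539),
    "C": ("C14H27NO3Na+", 280.1883),
    "D": ("C14H24NO+", 222.1852),
    "E": ("C16H31NO3Na+", 308.2196),
    "F": ("C7H11ClO3Na+", 201.0289),
}


@pytest.fixture(scope="session")
def table():
    return default_table()


@pytest.fixture(scope="session")
def calibrants():
    return default_calibrants()


@pytest.fixture(scope="session")
def qqq_shape():
    return PeakShapeModel.from_resolving_power(500.0)


@pytest.fixture
def gaussian_spectrum():
    """Factory: profile spectrum of Gaussian peaks on a uniform grid."""

    def make(peaks, lo=150.0, hi=350.0, step=0.01, fwhm_b=1 / 500, baseline=0.0):
        shape = PeakShapeModel(fwhm_b=fwhm_b)
        grid = np.arange(lo, hi + step / 2, step)
        intensity = np.full_like(grid, baseline)
        for center, area in peaks:
            intensity = intensity + shape.evaluate(grid, center, area)
        return ProfileSpectrum(grid, intensity, {})

    return make


def parse(text: str) -> Formula:
    return Formula.parse(text)
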