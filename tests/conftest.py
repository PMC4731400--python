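import numpy as np
import pytest

from thyrodos import InstrumentConfig, MediumConfig, OpticalProperties
from thyrodos.simulate import generate_irf


@pytest.fixture(scope="session")
def medium():
    return MediumConfig()


@pytest.fixture(scope="session")
def instrument():
    return InstrumentConfig()


@pytest.fixture(scope="session")
def irfs(instrument):
    """One exGaussian IRF per instrument wavelength on the TCSPC grid."""
    return {
        wl: generate_irf(instrument.pulse_width(wl), instrument.time_axis_ns, wl)
        for wl in instrument.wavelengths_nm
    }


@pytest.fixture(scope="session")
def tissue_props():
    """Optical properties representative of thyroid tissue at 785 nm."""
    return OpticalProperties(785.0, 0.25, 8.0)


@pytest.fixture(scope="session")
def times_ns():
    return np.linspace(0.05, 8.0, 800)
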