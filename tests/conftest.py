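import numpy as np
import pytest

from tsng.calibration import DEFAULT_CALIBRANTS
from tsng.glycans import default_library
from tsng.simulate import (
    CohortDesign,
    InstrumentModel,
    select_resolved_subset,
    serum_base_profile,
)


@pytest.fixture(scope="session")
def library():
    return default_library()


@pytest.fixture(scope="session")
def base_profile(library):
    return serum_base_profile(library)


@pytest.fixture(scope="session")
def resolved_lib40(library):
    """40 mass-resolved abundant analytes incl. all calibrants, m/z < 3650."""
    lib = [e for e in library if 1950 < e.mz < 3650]
    return select_resolved_subset(lib, 40, must_include=DEFAULT_CALIBRANTS)


@pytest.fixture(scope="session")
def reduced_instrument():
    """Narrow-range instrument used by the reduced simulation designs."""
    return InstrumentModel(mz_range=(1900.0, 3700.0), step=0.02, seed=0)


@pytest.fixture
def quiet_instrument():
    """Noise-free, perfectly calibrated instrument over the reduced range."""
    return InstrumentModel(
        mz_range=(1900.0, 3700.0),
        step=0.02,
        baseline_coeffs=(0.0,),
        noise_sd=0.0,
        seed=0,
    )
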