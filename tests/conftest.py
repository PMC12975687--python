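import numpy as np
import pytest

from plaquefilm.calibration import CalibrationCurve
from plaquefilm.plaque_geometry import load_model
from plaquefilm.synthetic_data import SyntheticSpec


@pytest.fixture(scope="session")
def cca():
    return load_model("CCA")


@pytest.fixture(scope="session")
def cob():
    return load_model("COB")


@pytest.fixture(scope="session")
def cib():
    return load_model("CIB")


@pytest.fixture
def rng():
    return np.random.default_rng(20260924)


@pytest.fixture
def inverse_curve():
    """The worked inverse curve used in the arithmetic oracles."""
    return CalibrationCurve(form="inverse", a=5.0, b=40.0, n=2.2, sd_a=0.1, sd_b=1.0, dose_range_Gy=(0.0, 3.0), r2=0.99999)


@pytest.fixture
def cca_spec(cca):
    return SyntheticSpec(model=cca, seed=1234)
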