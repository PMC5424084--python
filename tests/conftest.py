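import numpy as np
import pytest

from herbphys.farquhar import DEFAULT_CONSTANTS
from herbphys.simulate import ACiTruth, LightCurveTruth


@pytest.fixture
def light_truth():
    return LightCurveTruth(a_max=9.40, phi=0.077, r_d=0.52, theta=0.9)


@pytest.fixture
def aci_truth():
    return ACiTruth(v_cmax=27.73, j_max=43.49, r_day=0.5)


@pytest.fixture
def constants():
    return DEFAULT_CONSTANTS


@pytest.fixture
def rng():
    return np.random.default_rng(20150601)
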