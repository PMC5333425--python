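import numpy as np
import pytest

from citradose.domain import PatientState
from citradose.simulator import SimConfig, calibrate_chelation, calibration_curve


@pytest.fixture(scope="session")
def params():
    """Chelation mechanism calibrated to the anchor dosing case."""
    return calibrate_chelation()


@pytest.fixture(scope="session")
def cal_curve(params):
    """Ratio curve fitted on the noise-free titrated calibration set."""
    return calibration_curve(params)


@pytest.fixture()
def sim_config(params):
    return SimConfig(params=params)


@pytest.fixture()
def patient():
    return PatientState(patient_id="P1", hematocrit=0.30, pcai0=1.0)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
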