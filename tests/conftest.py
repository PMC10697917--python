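import numpy as np
import pytest

from hiptension.sensors import CalibrationModel
from hiptension.synth import generate_recording, patient4_spec


@pytest.fixture(scope="session")
def default_cal() -> CalibrationModel:
    return CalibrationModel()


@pytest.fixture(scope="session")
def noiseless_patient4(default_cal):
    """Noiseless synthetic trial for the smallest measured patient."""
    spec = patient4_spec()
    rec, truth = generate_recording(spec, default_cal)
    return spec, rec, truth


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20230901)
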