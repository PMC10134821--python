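import numpy as np
import pytest

from biomesim import DiffusionSystem, default_strains
from biomesim.plate_io import CalibrationCurve


@pytest.fixture
def dye_geometry() -> DiffusionSystem:
    """Standard dye-loading geometry: 400 uM in the left 250-uL well."""
    return DiffusionSystem(d=0.0, v_left=2.5e-4, v_right=2.5e-4,
                           c_left0=0.4, c_right0=0.0)


@pytest.fixture
def unit_calibration() -> CalibrationCurve:
    """The synthetic generator's default dye line: 1 OD per mmol/L."""
    return CalibrationCurve(slope=1.0, intercept=0.05, r_squared=1.0)


@pytest.fixture
def strains():
    return default_strains()


@pytest.fixture
def schedule_72h() -> np.ndarray:
    return np.round(np.arange(0.0, 72.25, 0.25), 10)
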