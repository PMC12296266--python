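import warnings

import pytest
from hypothesis import settings

from pbsdose import BeamlineConfig, CalibrationParams, SpotShapeModel
from pbsdose._validation import EnergyRangeWarning

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def config():
    return BeamlineConfig()


@pytest.fixture(scope="session")
def calibration():
    return CalibrationParams()


@pytest.fixture(scope="session")
def spot_model():
    return SpotShapeModel()


@pytest.fixture(autouse=True)
def _quiet_range_warnings():
    """Extrapolation warnings are contract-tested explicitly; keep runs quiet."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", EnergyRangeWarning)
        yield


@pytest.fixture(scope="session")
def paper_design():
    """Calibration design at commissioning scale: full energy grid, three
    currents, eight doses, five repeats."""
    energies = [float(e) for e in range(70, 241, 10)] + [245.0]
    currents = (50.0, 200.0, 800.0)
    doses = (0.25, 0.5, 1.0, 2.0, 4.0, 8.0, 12.0, 16.0)
    return [
        (e, ic, d)
        for e in energies
        for ic in currents
        for d in doses
        for _ in range(5)
    ]
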