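import numpy as np
import pytest

from crystaldepot import CrystalDepot, PKParameters


@pytest.fixture
def default_params() -> PKParameters:
    """Human-vitreous scenario: 9.5-day half-life, calibrated transfer coefficient."""
    return PKParameters.from_half_life(9.5, h=0.5, V=4.5, Cs=0.08, C_threshold=0.01)


@pytest.fixture
def lamellar_depot() -> CrystalDepot:
    return CrystalDepot(M0=5.0, A0=2.0, geometry_mode="lamellar")


@pytest.fixture
def day_grid():
    return np.linspace(0.0, 120.0, 481)
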