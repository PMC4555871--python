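import numpy as np
import pytest

from tgtquant import sensors, simulate


@pytest.fixture(scope="session")
def panel():
    return sensors.build_sensor_panel()


@pytest.fixture(scope="session")
def panel_with_control():
    return sensors.build_sensor_panel(include_control=True)


@pytest.fixture
def small_optics():
    """Compact frame for fast rendering; same pixel/PSF scale as defaults."""
    return simulate.OpticsModel(frame_shape=(96, 96))


@pytest.fixture
def cell_optics():
    """Frame large enough to hold a full synapse footprint."""
    return simulate.OpticsModel(frame_shape=(128, 128))
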