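import numpy as np
import pytest

from lumenflow.kinematics import MotilityCase, derive_geometry


@pytest.fixture(scope="session")
def seg_geom():
    """Baseline segmentation geometry: 2 mL pocket, 2.4 cm wave, OR 0.3."""
    return derive_geometry(2.0, 2.4, 0.3, "segmentation", period=5.0)


@pytest.fixture(scope="session")
def seg_geom_10ml():
    return derive_geometry(10.0, 4.1, 0.3, "segmentation", period=5.0)


@pytest.fixture(scope="session")
def peri_geom():
    """Moderate peristalsis on the 2 mL pocket pairing."""
    return derive_geometry(2.0, 2.4, 0.3, "peristalsis", wave_speed=1.0)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
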