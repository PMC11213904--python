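import numpy as np
import pytest

from fullfield import geometry as geo
from fullfield import synthetic, warp


@pytest.fixture(scope="session")
def screen():
    return geo.ScreenGeometry()


@pytest.fixture(scope="session")
def nominal_view():
    return geo.ViewingGeometry(eye_to_screen_cm=15.0)


@pytest.fixture(scope="session")
def projection():
    return geo.ProjectionGeometry()


@pytest.fixture(scope="session")
def ref_model(screen):
    """Warp model calibrated from the reference installation, noise-free."""
    return warp.fit_calibration(synthetic.synth_calibration())


@pytest.fixture(scope="session")
def ref_map(ref_model):
    """Full-raster warp map for the reference installation (built once)."""
    return warp.build_warp_map(ref_model)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
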