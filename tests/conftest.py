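import pytest

from ledhsi.calibration import flat_field_calibrate
from ledhsi.instrument import CameraModel, GeometryConfig, default_led_array
from ledhsi.simulate import (
    acquire_dark,
    acquire_hypercube,
    acquire_white,
    make_phantom,
)

ROWS = COLS = 64


@pytest.fixture(scope="session")
def led_array():
    return default_led_array()


@pytest.fixture(scope="session")
def camera():
    return CameraModel(rows=ROWS, cols=COLS)


@pytest.fixture(scope="session")
def geometry():
    return GeometryConfig()


@pytest.fixture(scope="session")
def noiseless_session(led_array, camera, geometry):
    """One complete noise-free acquisition: phantom + dark + white + raw + cal."""
    phantom = make_phantom(ROWS, COLS, n_tissues=2, glare_spots=3, seed=3,
                           led_array=led_array, camera=camera)
    dark = acquire_dark(camera, shape=(ROWS, COLS), noise_on=False, seed=0)
    white = acquire_white(led_array, camera, geometry, shape=(ROWS, COLS),
                          noise_on=False, seed=0)
    raw = acquire_hypercube(phantom, led_array, camera, geometry,
                            noise_on=False, seed=0)
    cal = flat_field_calibrate(raw, dark, white)
    return {
        "phantom": phantom,
        "dark": dark,
        "white": white,
        "raw": raw,
        "cal": cal,
        "denominator": white.data.astype(float) - dark.data.astype(float)[..., None],
    }
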