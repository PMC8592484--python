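import numpy as np
import pytest

from pushtrack.geometry import CalibrationSet, look_at_camera
from pushtrack.synthetic import make_camera_ring


@pytest.fixture(scope="session")
def small_ring() -> CalibrationSet:
    """Four cameras at reduced resolution: cheap but fully multi-view."""
    return make_camera_ring(n=4, image_size=(480, 270))


@pytest.fixture(scope="session")
def full_ring() -> CalibrationSet:
    """The standard nine-camera ring at the default working resolution."""
    return make_camera_ring()


@pytest.fixture()
def quad_cameras() -> list:
    """Four hand-placed cameras around the origin for geometry tests."""
    cams = []
    for i, pos in enumerate([(0, -5, 1), (5, 3, 2), (-4, 4, 1.5), (2, -6, 0.5)]):
        cams.append(
            look_at_camera(f"g{i}", np.array(pos, float),
                           np.array([0.5, 0.2, 0.8]), 480.0, (960, 540))
        )
    return cams
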