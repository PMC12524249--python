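import numpy as np
import pytest

from dualview import scene_sim
from dualview.camera_geometry import CameraModel
from dualview.scene_sim import PenConfig


@pytest.fixture
def pen() -> PenConfig:
    return PenConfig()


@pytest.fixture
def cameras(pen):
    """(top, pan) study cameras: ceiling camera 3.4 m over the feeding
    area and the oblique panoramic camera."""
    return scene_sim.default_cameras(pen)


@pytest.fixture
def simple_top() -> CameraModel:
    """Camera 3.4 m above the origin looking straight down (world +X →
    image +x, world +Y → image +y)."""
    return CameraModel.from_intrinsics(
        fx=1000.0, fy=1000.0, cx=960.0, cy=540.0,
        R=np.diag([1.0, 1.0, 1.0]), T=(0.0, 0.0, 3.4),
        image_size=(1920, 1080))
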