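import numpy as np
import pytest

from esrrf import CameraModel, GroundTruthScene, ReconstructionSettings
from esrrf.simulate import BlinkTrace


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def gaussian_spot_frame():
    """A 17x17 frame with one symmetric Gaussian spot (sigma = 1 raw px)
    centered on the middle pixel."""
    yy, xx = np.mgrid[:17, :17]
    return 100.0 * np.exp(-(((yy - 8) ** 2 + (xx - 8) ** 2) / 2.0))


@pytest.fixture
def default_settings():
    return ReconstructionSettings(magnification=4, radius=1.5, sensitivity=2.0)


@pytest.fixture
def noiseless_camera():
    return CameraModel(exposure=0.010, read_time=0.0, offset=0.0, read_noise=0.0)


def always_on_trace(duration: float) -> BlinkTrace:
    return BlinkTrace(on_intervals=[(0.0, duration)], bleach_time_drawn=np.inf,
                      bleach_time=np.inf, duration=duration)


@pytest.fixture
def single_emitter_scene():
    return GroundTruthScene(coords=[[800.0, 800.0]], extent=(1600.0, 1600.0))
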