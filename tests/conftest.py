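import numpy as np
import pytest

from hemoflow.video_io import CalibrationProfile, FrameStack


@pytest.fixture
def calib():
    """Standard study-like calibration: 1 μm per pixel at 60 fps."""
    return CalibrationProfile(pixel_scale_um=1.0, frame_rate_fps=60.0)


@pytest.fixture
def calib2():
    """Coarser calibration used by the band-diameter oracles."""
    return CalibrationProfile(pixel_scale_um=2.0, frame_rate_fps=60.0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def textured_frame(rng):
    """A smooth random frame with enough texture to register on."""
    from scipy import ndimage

    f = ndimage.gaussian_filter(rng.random((96, 128)), 2.0)
    return (f - f.min()) / np.ptp(f)


def make_stack(frames, calibration):
    return FrameStack(np.clip(np.asarray(frames), 0.0, 1.0), calibration)
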