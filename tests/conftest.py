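import numpy as np
import pytest

from sofiquant.stack_io import AcquisitionConfig, ImageSequence


@pytest.fixture
def optics():
    return AcquisitionConfig()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def gaussian_spot(shape, cy, cx, sigma_px, amplitude=1.0):
    """Sampled (not pixel-integrated) Gaussian peak, for optics fixtures."""
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    return amplitude * np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2)
                              / (2.0 * sigma_px ** 2))


@pytest.fixture
def bead_sequence(optics):
    """Short sequence with one bright immobile bead and dim background."""
    T, H, W = 60, 32, 32
    frames = np.full((T, H, W), 0.5)
    frames += gaussian_spot((H, W), 12.7, 10.3, 1.2, amplitude=200.0)[None]
    return ImageSequence(frames, pixel_pitch_nm=optics.pixel_pitch_nm)
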