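import numpy as np
import pytest

from wallmorph.core import CalibratedImage, ROI
from wallmorph.synthetic import TemWallTruth


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_image(rng):
    return CalibratedImage(rng.uniform(0, 255, size=(40, 50)), 0.5, units="um")


def tem_truth(void_fraction: float) -> TemWallTruth:
    """Well-separated bright-void TEM truth on a 256x256 canvas."""
    return TemWallTruth(
        void_fraction=void_fraction,
        void_intensity_mean=200.0,
        void_intensity_sd=8.0,
        wall_intensity_mean=80.0,
        wall_intensity_sd=12.0,
        void_reference_roi=ROI(4, 4, 60, 250),
        intra_wall_roi=ROI(120, 4, 250, 250),
    )
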