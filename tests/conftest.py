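import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from viatrace import IntensityImage, PixelDoseModel, SegmentationParams

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=30,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture
def model():
    """Beer-Lambert dose model at a round epsilon for closed-form checks."""
    return PixelDoseModel(epsilon=2500.0, pixel_size=1.0)


@pytest.fixture
def seg_params():
    return SegmentationParams(sensitivity=0.45)


@pytest.fixture
def uniform_triplet():
    """Noise-free 64x64 triplet with a uniform transmittance of 0.1."""
    shape = (64, 64)
    blank = IntensityImage(np.full(shape, 30000.0), 16, 0.65, "blank")
    dark = IntensityImage(np.zeros(shape), 16, 0.65, "dark")
    sample = IntensityImage(np.full(shape, 3000.0), 16, 0.65, "sample")
    return sample, blank, dark
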