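import numpy as np
import pytest
from PIL import Image

from pearlhue import BackgroundPolicy, hsv_to_rgb


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


@pytest.fixture
def lossless_policy():
    """Background = pure white only; right for PNG fixtures."""
    return BackgroundPolicy(tau=255)


@pytest.fixture
def make_uniform_image(tmp_path):
    """Write a PNG with a centred uniform square of a given HSV on white."""

    def _make(hsv, name="sample", canvas=32, side=12):
        rgb = hsv_to_rgb(hsv).as_tuple()
        pixels = np.full((canvas, canvas, 3), 255, dtype=np.uint8)
        lo = (canvas - side) // 2
        pixels[lo:lo + side, lo:lo + side] = rgb
        path = tmp_path / f"{name}.png"
        Image.fromarray(pixels).save(path)
        return path

    return _make
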