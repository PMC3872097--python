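import numpy as np
import pytest

from tendoqus import ImageRecord


def make_image(pixels, spacing=(0.02, 0.02), view="transverse", **kw) -> ImageRecord:
    return ImageRecord(
        pixels=np.asarray(pixels, dtype=np.uint8), spacing_mm=spacing, view=view, **kw
    )


@pytest.fixture()
def uniform_image():
    """64x64 constant-128 transverse frame at 0.02 mm/px."""
    return make_image(np.full((64, 64), 128), spacing=(0.02, 0.02))


@pytest.fixture()
def rng():
    return np.random.default_rng(20260920)
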