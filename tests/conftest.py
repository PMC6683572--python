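import numpy as np
import pytest

from coverimg import Raster, Selection


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def random_raster(rng):
    def _make(width=16, height=16, dpi=None, seed=None):
        r = np.random.default_rng(seed) if seed is not None else rng
        pixels = r.integers(0, 256, size=(height, width, 3), dtype=np.uint8)
        return Raster(pixels=pixels, dpi=dpi)

    return _make


@pytest.fixture
def basic_selection():
    return Selection(
        name="basic",
        include=((52, 130, 60),),
        ignore=((255, 255, 255),),
        metric="rgb",
        tolerance=35.0,
    )
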