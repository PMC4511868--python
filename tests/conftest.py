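import numpy as np
import pytest

from hypersr import HyperCube, MapImage


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_cube(rng, ny=3, nx=4, nw=6, pixel_size=1.0, origin=(0.0, 0.0)):
    axis = 900.0 + 5.0 * np.arange(nw)
    return HyperCube(rng.random((ny, nx, nw)), axis,
                     pixel_size=pixel_size, origin=origin)


@pytest.fixture
def small_cube(rng):
    return random_cube(rng)


@pytest.fixture
def flat_map():
    return MapImage(np.full((6, 6), 2.5), pixel_size=0.5)
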