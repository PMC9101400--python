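import numpy as np
import pytest

from pollenraman import HyperspectralImage, WavenumberAxis, simulate_phantom


@pytest.fixture(scope="session")
def default_phantom():
    """One default-size phantom shared by read-only tests."""
    img, truth, comps = simulate_phantom(seed=1)
    return img, truth, comps


@pytest.fixture
def toy_axis():
    return WavenumberAxis(np.linspace(400.0, 3100.0, 28))


def make_image(axis, data, width=None, height=None, **kw):
    data = np.atleast_2d(np.asarray(data, dtype=float))
    n = data.shape[0]
    if width is None:
        width, height = n, 1
    return HyperspectralImage(width=width, height=height, axis=axis,
                              data=data, **kw)


@pytest.fixture
def image_factory():
    return make_image
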