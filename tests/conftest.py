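import numpy as np
import pytest

from tpsreg.imaging import Image2D
from tpsreg.phantoms import PhantomSpec, make_phantom


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def smooth_image():
    """A smooth 64x64 test image (band-limited, so bilinear loss is small)."""
    yy, xx = np.mgrid[0:64, 0:64]
    arr = 0.5 + 0.35 * np.sin(xx / 9.0) * np.cos(yy / 11.0) + 0.1 * np.sin(
        (xx + 2 * yy) / 17.0
    )
    return Image2D.from_array(arr)


@pytest.fixture(scope="session")
def noise_image():
    rng = np.random.default_rng(7)
    return Image2D.from_array(rng.random((33, 33)), normalize=False)


@pytest.fixture(scope="session")
def small_phantom():
    """64x64 noiseless phantom with labels; fast enough for optimizer tests."""
    spec = PhantomSpec(size=64, noise_sd=0.0, seed=3)
    img, labels = make_phantom(spec)
    return img, labels, spec


@pytest.fixture(scope="session")
def phantom128():
    spec = PhantomSpec(size=128, noise_sd=0.01, seed=0)
    img, labels = make_phantom(spec)
    return img, labels, spec
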