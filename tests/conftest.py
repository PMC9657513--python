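import numpy as np
import pytest

import thermolesion as tl


@pytest.fixture
def square_contour():
    """Unit square with the closing vertex duplicated."""
    return tl.IsothermContour(
        level=36.5,
        vertices=np.array([[0, 0], [1, 0], [1, 1], [0, 1], [0, 0]], dtype=float),
    )


@pytest.fixture
def lesion_spec():
    """Single noiseless Gaussian lesion (sigma 15 px, amplitude 1 °C)."""
    return tl.PhantomSpec(
        height=160,
        width=160,
        lesions=(tl.GaussianLesion(x=80.0, y=80.0, sigma=15.0, amplitude=1.0),),
        noise_sd=0.0,
        seed=7,
    )


@pytest.fixture
def lesion_phantom(lesion_spec):
    return tl.generate_phantom(lesion_spec)


@pytest.fixture
def scene_spec():
    """Phantom with a cool background border around an inner skin patch."""
    return tl.PhantomSpec(
        height=120,
        width=120,
        skin_region=tl.SkinRegion("rect", 10, 10, 100, 100),
        lesions=(tl.GaussianLesion(x=60.0, y=60.0, sigma=12.0, amplitude=1.0),),
        noise_sd=0.0,
        seed=3,
    )


def uniform_frame(value=36.0, shape=(8, 8), **meta):
    return tl.ThermalFrame(grid=np.full(shape, float(value)), **meta)
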