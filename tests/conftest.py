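import numpy as np
import pytest

from mechanomics import DensityImage, PhantomSpec


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def random_image(rng):
    return DensityImage(rng.uniform(0, 800, size=(7, 7, 7)))


@pytest.fixture
def phantom_spec():
    # Small three-frame phantom: growth then partial resorption.
    return PhantomSpec(
        shape=(30, 30, 36),
        cortex_outer_radius=110.0,
        cortex_inner_radius=70.0,
        gap_height=100.0,
        callus_radii=(0.0, 140.0, 130.0),
    )
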