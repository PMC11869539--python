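import numpy as np
import pytest

from imlts.phantom import Nodule, PhantomSpec, generate_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def simple_phantom():
    """One noise-free 5 mm nodule at 0.5 mm spacing."""
    spec = PhantomSpec(
        image_shape=(128, 128),
        spacing_mm=(0.5, 0.5),
        nodules=(Nodule((64.0, 64.0), 5.0),),
        noise_sigma=0.0,
        seed=0,
    )
    img, mask, labels = generate_phantom(spec)
    return spec, img, mask, labels


@pytest.fixture
def noisy_phantom():
    """Same geometry with sigma-20 Gaussian noise."""
    spec = PhantomSpec(
        image_shape=(128, 128),
        spacing_mm=(0.5, 0.5),
        nodules=(Nodule((64.0, 64.0), 8.0),),
        noise_sigma=20.0,
        seed=1,
    )
    img, mask, labels = generate_phantom(spec)
    return spec, img, mask, labels
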