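import numpy as np
import pytest

from piddpm.acquisition import AcquisitionModel
from piddpm.optics import OpticalConfig, PSFVolume


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def base_config():
    """A well-sampled mid-NA configuration used across optics tests."""
    return OpticalConfig(
        numerical_aperture=0.8,
        lambda_ex=488.0,
        lambda_em=520.0,
        refractive_index=1.33,
        pixel_size_xy=0.04,
        grid_shape=(1, 128, 128),
    )


@pytest.fixture
def delta_model():
    """Acquisition model whose kernel is a discrete delta (A = identity)."""
    k = np.zeros((5, 5))
    k[2, 2] = 1.0
    return AcquisitionModel(psf=PSFVolume(k[None], (1.0, 0.1, 0.1)))


@pytest.fixture
def blur_model(rng):
    """Random positive 5x5 unit-sum kernel."""
    k = rng.random((5, 5)) + 0.1
    k /= k.sum()
    return AcquisitionModel(psf=PSFVolume(k[None], (1.0, 0.1, 0.1)))
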