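import numpy as np
import pytest

from discgap.phantom import PhantomParams, generate_spine_mask


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def straight_params():
    """Noiseless phantom on a straight vertical centerline."""
    return PhantomParams(
        curve_coeffs=(256.0, 0.0, 0.0, 0.0, 0.0),
        jitter_px=0.0,
        speck_rate=0,
        seed=7,
    )


@pytest.fixture
def straight_phantom(straight_params):
    return generate_spine_mask(straight_params)


@pytest.fixture
def small_model_config():
    """Cheap architecture for tests that only exercise plumbing."""
    from discgap.model import ModelConfig

    return ModelConfig(kernel_size=31, channels=8)
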