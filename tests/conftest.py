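import numpy as np
import pytest

from tangleseg import ModelConfig, SyntheticParams, TrainConfig, generate_sample


@pytest.fixture(scope="session")
def tiny_model_config():
    """Smallest config that still exercises pooling, skips and four decoders."""
    return ModelConfig(input_size=16, base_filters=2, depth=3, kernel_size=3)


@pytest.fixture(scope="session")
def tiny_train_config():
    return TrainConfig(epochs=1, batch_size=2, learning_rate=1e-3, resize_to=16)


@pytest.fixture(scope="session")
def tiny_synth_params():
    return SyntheticParams(image_size=16, n_cores=2, core_radius_range=(3, 5),
                           background_noise_sigma=0.02, rng_seed=7)


@pytest.fixture(scope="session")
def tiny_sample(tiny_synth_params):
    return generate_sample(tiny_synth_params, 0)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
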