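import numpy as np
import pytest

from myoscreen import FieldSimConfig, simulate_field

# compact geometry used across tests: one field renders in tens of ms
SMALL_FIELD = dict(
    canvas_size=(256, 256),
    n_muscles=2,
    muscle_length_range=(70.0, 130.0),
    n_nonmuscle_cells=15,
)


@pytest.fixture
def small_config():
    return FieldSimConfig(**SMALL_FIELD, seed=11)


@pytest.fixture
def noise_free_config():
    return FieldSimConfig(**SMALL_FIELD, noise_sd=0.0, seed=11)


@pytest.fixture
def noise_free_field(noise_free_config):
    return simulate_field(noise_free_config)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
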