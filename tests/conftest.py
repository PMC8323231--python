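import numpy as np
import pytest

from lesioncorrect.phantom import PhantomConfig, generate_dataset, generate_slice


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_config():
    """A small, quick phantom configuration."""
    return PhantomConfig(image_size=64, lesion_count_range=(1, 6), seed=7)


@pytest.fixture
def noise_free_config():
    return PhantomConfig(image_size=64, lesion_count_range=(3, 3), noise_sd=0.0, seed=7)


@pytest.fixture
def tiny_dataset(small_config):
    """10 patients x 2 slices with fixed type quotas; both classes present."""
    types = ["healthy"] * 3 + ["fci"] * 4 + ["laci"] * 3
    return generate_dataset(small_config, 10, 2, rng=np.random.default_rng(11),
                            patient_types=types)
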