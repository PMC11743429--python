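import numpy as np
import pytest

from organnet import CohortSpec, OrganNetConfig, SceneSpec, TrainConfig
from organnet.harness import TongueDataset
from organnet.synth import generate_cohort_arrays


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def small_model_config():
    return OrganNetConfig.small()


@pytest.fixture(scope="session")
def tiny_dataset():
    """A 240-sample 64x64 synthetic cohort for fast harness tests."""
    cohort = CohortSpec(n=240, splits=(180, 20, 40), seed=77)
    images, labels, splits = generate_cohort_arrays(cohort, SceneSpec(image_size=64))
    return TongueDataset(images, labels, splits)


@pytest.fixture(scope="session")
def quick_train_config():
    return TrainConfig.small(epochs=2, seed=0)


@pytest.fixture
def random_image(rng):
    return rng.integers(0, 256, (48, 40, 3), dtype=np.uint8)
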