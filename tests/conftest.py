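import numpy as np
import pytest

from aepseg.datatypes import SyntheticSpec
from aepseg.synthetic import generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_dataset_3c():
    """Eight 32x32 3-class fields for fast training-path tests."""
    spec = SyntheticSpec(
        num_classes=3, image_size=(32, 32), cell_count_range=(2, 3), seed=42
    )
    return generate_dataset(spec, n=8)


@pytest.fixture(scope="session")
def small_dataset_2c():
    spec = SyntheticSpec(
        num_classes=2, image_size=(32, 32), cell_count_range=(2, 3), seed=43
    )
    return generate_dataset(spec, n=8)
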