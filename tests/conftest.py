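import numpy as np
import pytest

from paomni.dataset import TaskSpec, build_dataset


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_bundle():
    """A small ring-16 dataset shared by training-protocol tests."""
    task = TaskSpec(geometry="ring", n_sparse=16, n_dense=64, grid_size=(32, 32))
    return build_dataset(n_items=30, n_groups=6, task=task,
                         split_fractions=(0.5, 0.3, 0.2), seed=7)


@pytest.fixture
def image_pair_32(rng):
    """Two random co-shaped 32x32 images in [0, 1]."""
    return rng.random((32, 32)), rng.random((32, 32))
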