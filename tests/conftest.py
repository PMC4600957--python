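import numpy as np
import pytest

from poroarch import VoxelVolume


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_volume(rng):
    """A 32³ random binary volume with ~60% pores."""
    mask = rng.random((32, 32, 32)) > 0.6
    return VoxelVolume(mask, voxel_size_um=10.0)
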