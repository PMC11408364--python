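import numpy as np
import pytest

from zcoloc import ChannelVolume, ZStack


@pytest.fixture
def rng():
    return np.random.default_rng(20241001)


def make_stack(arrays, name="test", spacing=None):
    """Build a ZStack from a list of 3D numpy arrays (one per channel)."""
    channels = [ChannelVolume(index=i + 1, voxels=np.asarray(a))
                for i, a in enumerate(arrays)]
    return ZStack(channels=channels, name=name, voxel_spacing=spacing)


def random_stack(rng, n_channels=2, dims=(4, 6, 6), dtype=np.uint8, high=None):
    """Random integer stack for oracle-equivalence tests."""
    high = high if high is not None else np.iinfo(dtype).max
    arrays = [rng.integers(0, high + 1, size=dims).astype(dtype)
              for _ in range(n_channels)]
    return make_stack(arrays)
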