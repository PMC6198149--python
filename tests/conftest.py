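import numpy as np
import pytest

from vastcore import ChunkedVolume, PhantomSpec, make_phantom
from vastcore.segments import table_from_volume


@pytest.fixture(scope="session")
def phantom():
    """Small deterministic phantom shared by read-only tests."""
    img, truth = make_phantom(PhantomSpec(dims=(48, 48, 24), seed=7))
    return img, truth


@pytest.fixture()
def small_seg():
    """A 32x32x8 segmentation with two labeled boxes and its table."""
    vol = ChunkedVolume((32, 32, 8), (6.0, 6.0, 30.0), "id16", 2)
    arr = np.zeros((32, 32, 8), dtype=np.uint16)
    arr[2:10, 2:10, 1:5] = 1
    arr[20:28, 20:26, 3:7] = 2
    vol.write_full(arr, 0)
    return vol, table_from_volume(vol)


def make_id_volume(arr: np.ndarray, num_levels: int = 1) -> ChunkedVolume:
    vol = ChunkedVolume(arr.shape, (6.0, 6.0, 30.0), "id16", num_levels)
    vol.write_full(arr.astype(np.uint16), 0)
    return vol
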