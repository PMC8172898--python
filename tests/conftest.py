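import numpy as np
import pytest

from radstab.core import CTVolume, ROIMask
from radstab.phantom import toy_fixtures


@pytest.fixture(scope="session")
def toy():
    return toy_fixtures()


def as_volume(arr, spacing=(1.0, 1.0, 1.0), case_id="t") -> CTVolume:
    """Lift a 2D or 3D integer array into a CTVolume (>= 2 slices)."""
    arr = np.asarray(arr)
    if arr.ndim == 2:
        arr = arr[None]
    if arr.shape[0] < 2:
        arr = np.repeat(arr, 2, axis=0)
    return CTVolume(arr, spacing, case_id)


def full_mask(vol: CTVolume, label="roi") -> ROIMask:
    return ROIMask(np.ones_like(vol.voxels, dtype=bool), vol.spacing, label)


@pytest.fixture
def rng():
    return np.random.default_rng(20210602)
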