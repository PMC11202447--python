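import numpy as np
import pytest

from mamlseg.backbone import BackboneConfig
from mamlseg.volume_io import BinaryMask, Volume


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_backbone_cfg():
    """Smallest legal U-Net: 2 levels, 1 residual subunit, no dropout, float64."""
    return BackboneConfig(channels=(4, 8), strides=(2,), num_res_units=1,
                          dropout=0.0, dtype="float64")


def random_mask(rng, shape=(20, 20, 20), p=0.2, spacing=(1.0, 1.0, 1.0)):
    return BinaryMask(data=(rng.random(shape) < p).astype(np.uint8), spacing=spacing)


def blob_mask(center, radius, shape=(20, 20, 20), spacing=(1.0, 1.0, 1.0)):
    grid = np.stack(np.meshgrid(*[np.arange(s) for s in shape], indexing="ij"))
    d2 = sum((grid[i] - center[i]) ** 2 for i in range(3))
    return BinaryMask(data=(d2 <= radius ** 2).astype(np.uint8), spacing=spacing)


@pytest.fixture
def volume(rng):
    return Volume(data=rng.normal(0, 100, size=(16, 16, 16)).astype(np.float32),
                  spacing=(1.5, 1.5, 1.5))
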