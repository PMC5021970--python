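import numpy as np
import pytest

from mitoganglia.io import VoxelGeometry


@pytest.fixture
def geometry():
    """The confocal geometry the pipeline targets: 0.1 μm pixels, 0.18 μm z."""
    return VoxelGeometry(0.1, 0.1, 0.18)


@pytest.fixture
def unit_geometry():
    return VoxelGeometry(1.0, 1.0, 1.0)


@pytest.fixture
def rng():
    return np.random.default_rng(20160914)
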