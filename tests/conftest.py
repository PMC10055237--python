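import numpy as np
import pytest

from videobp.roi_maps import SpatioTemporalMap


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def random_map(rng):
    """A random RGB spatiotemporal map: 4 ROIs x 450 frames x 3 channels."""
    values = rng.uniform(0.0, 255.0, size=(4, 450, 3))
    return SpatioTemporalMap(values=values, channel_space="RGB", fps=30.0)


@pytest.fixture
def small_map(rng):
    values = rng.uniform(0.0, 255.0, size=(4, 40, 3))
    return SpatioTemporalMap(values=values, channel_space="RGB", fps=30.0)
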