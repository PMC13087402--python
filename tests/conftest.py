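import numpy as np
import pytest

from qsarkit import DescriptorTable


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_table():
    return DescriptorTable(
        ["c1", "c2", "c3"],
        ["d1", "d2"],
        [[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]],
    )


@pytest.fixture
def tree_table():
    """Rows spanning the three leaves of the published classification rule."""
    return DescriptorTable(
        ["lo", "hi-lo", "hi-hi", "edge"],
        ["X4sol", "VR2_Dzi", "unused"],
        [
            [7.0, 5.0, 0.0],    # shallow active leaf
            [8.0, 11.0, 1.0],   # inactive leaf
            [8.0, 12.0, 2.0],   # deep active leaf
            [7.564, 99.0, 3.0], # exactly on root threshold -> left (active)
        ],
    )
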