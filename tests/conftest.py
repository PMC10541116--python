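import numpy as np
import pytest

from axoxl.io_formats import Structure

from helpers import make_chain


@pytest.fixture
def toy_structure():
    """Two chains of 4 residues on a simple grid."""
    a = make_chain([(0, 0, 0), (3, 4, 0), (10, 0, 0), (0, 0, 50)], "A")
    b = make_chain([(1, 0, 0), (0, 0, 200), (5, 5, 5), (8, 0, 0)], "B")
    return Structure(id="toy", chains=[a, b])


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
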