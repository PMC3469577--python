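import numpy as np
import pytest

from mirseed.simulate import make_reference

ADAPTER = "TGGAATTCTCGGGTGCCAAGG"


@pytest.fixture(scope="session")
def small_truth():
    """A small synthetic study truth shared by read-only tests."""
    return make_reference(8, 12, seed=3)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
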