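import numpy as np
import pytest

from bpfuse.phantoms import PhantomSpec, make_pair
from bpfuse.training import FusionRecord


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_gray(rng, h, w):
    return rng.random((h, w))


def random_color(rng, h, w):
    return rng.random((h, w, 3))


@pytest.fixture(scope="session")
def phantom_pair_64():
    """One co-registered 64x64 structural/functional pair."""
    spec = PhantomSpec(size=(64, 64), blob_sigma=5.0, seed=42)
    return make_pair(spec)


@pytest.fixture(scope="session")
def phantom_records_32():
    """Eight small co-registered pairs for fast training smoke tests."""
    recs = []
    for k in range(8):
        spec = PhantomSpec(size=(32, 32), n_structures=3, blob_sigma=3.0,
                           seed=500 + k)
        s, f = make_pair(spec)
        recs.append(FusionRecord(s, f))
    return recs
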