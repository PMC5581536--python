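import numpy as np
import pytest

from pairtrim.records import ReadRecord


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)


def random_seq(rng, n, alphabet="ACGT"):
    return "".join(alphabet[i] for i in rng.integers(0, len(alphabet), n))


def make_read(bases, name="r", quality=30, mate=None):
    return ReadRecord(name, bases, np.full(len(bases), quality,
                                           dtype=np.uint8), mate)


@pytest.fixture
def seq_factory():
    return random_seq


@pytest.fixture
def read_factory():
    return make_read
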