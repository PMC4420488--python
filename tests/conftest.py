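import numpy as np
import pytest

from ligbias import StackingBackend, pool_from_sequences
from ligbias.adaptors import AdaptorSpec


@pytest.fixture(scope="session")
def toy_backend():
    return StackingBackend()


@pytest.fixture
def small_pool():
    return pool_from_sequences(
        {
            "m1": "ACGUACGUACGUACGUACGU",
            "m2": "GGGCAUCGAUCGAUAGCUAG",
            "m3": "UUUACGGAUCCGUAAACGGA",
        }
    )


@pytest.fixture
def adaptor3():
    # defined 3' DNA adaptor (pre-adenylated in the wet protocol)
    return AdaptorSpec(
        side="three_prime", sequence="AGATCGGAAGAGCACACGTCT", alphabet="DNA", name="a3"
    )


@pytest.fixture
def adaptor5():
    return AdaptorSpec(
        side="five_prime", sequence="GUUCAGAGUUCUACAGUCCGACGAUC", alphabet="RNA", name="a5"
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
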