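import numpy as np
import pytest

from pairmhn.model import EventSystem, ParameterSet


def genotypes(n):
    """All 2**n binary genotypes of length n, as int8 arrays."""
    return [
        np.array([(g >> i) & 1 for i in range(n)], dtype=np.int8)
        for g in range(1 << n)
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def sys2():
    return EventSystem(2)


@pytest.fixture
def random_params2(rng):
    return ParameterSet.random(2, rng)
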