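import numpy as np
import pytest

from funcmod.datatypes import GeneUniverse


@pytest.fixture
def universe10() -> GeneUniverse:
    return GeneUniverse(tuple(f"g{i}" for i in range(10)))


@pytest.fixture
def universe100() -> GeneUniverse:
    return GeneUniverse(tuple(f"g{i:03d}" for i in range(100)))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
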