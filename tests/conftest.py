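import numpy as np
import pytest

from rxnflow.reactions import Reaction, ReactionNetwork


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)


@pytest.fixture
def two_species_net():
    """a <=> b."""
    return ReactionNetwork(2, [Reaction((0,), (1,))])


@pytest.fixture
def chain_net():
    """a <=> b <=> c."""
    return ReactionNetwork(3, [Reaction((0,), (1,)), Reaction((1,), (2,))])
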