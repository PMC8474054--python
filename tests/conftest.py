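import numpy as np
import pytest

from polcond.config import ChainSpec, ScenarioConfig
from polcond.lattice import AffinityMatrix, LatticeState, initialize_state


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def defaults():
    return AffinityMatrix()


@pytest.fixture
def small_chain_state(rng):
    """10x10 lattice, one mixed 12-mer chain, 20 particles."""
    cfg = ScenarioConfig(width=10, height=10, n_s5p=20,
                         chains=[ChainSpec(n_rc=4, n_ac=3, length=12)],
                         layout="single", n_steps=0, seed=3)
    return initialize_state(cfg, rng), cfg


def make_particle_state(width, height, sites):
    state = LatticeState(width, height)
    for y, x in sites:
        state.add_particle(y, x)
    return state
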