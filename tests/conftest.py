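import numpy as np
import pytest

from tiptraffic.model import GDP, LatticeState, ModelParams


@pytest.fixture
def small_params():
    """A fast, fully featured parameter set for short test runs."""
    return ModelParams(L0=50, gamma=0.5, seed=7)


def make_state(length, motors=(), cargo=None, nucleotide=None):
    """Build a lattice state from site lists; cargo maps site -> stack height."""
    st = LatticeState.empty(length, GDP)
    for i in motors:
        st.motor[i] = 1
    for i, h in (cargo or {}).items():
        st.cargo[i] = h
    for i, nuc in (nucleotide or {}).items():
        st.nucleotide[i] = nuc
    return st


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
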