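import numpy as np
import pytest

from abxlattice import CellState, ModelParams


@pytest.fixture
def params():
    """Default parameter set used throughout: r1=2, r2=2.5, v=1, b=10."""
    return ModelParams()


@pytest.fixture
def two_strain_params():
    """P(a=110) + N parameter set on a small lattice."""
    return ModelParams(L=64, allowed_a=(0.0, 110.0), c=0.001, seed=1)


@pytest.fixture
def pns_composition():
    def make(a: float, fraction: float = 0.05):
        return [
            (CellState.producer(a), fraction),
            (CellState.nonproducer(), fraction),
            (CellState.sensitive(), fraction),
        ]

    return make


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
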