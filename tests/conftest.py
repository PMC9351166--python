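import numpy as np
import pytest

from urbanscan import synth


@pytest.fixture
def lattice_5x5():
    spec = synth.SimulationSpec(nx=5, ny=5, cell_size=1000.0, seed=3)
    return synth.make_lattice(spec)


@pytest.fixture
def lattice_12x12():
    spec = synth.SimulationSpec(nx=12, ny=12, cell_size=1000.0, seed=7)
    return synth.make_lattice(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
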