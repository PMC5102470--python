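import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def chain4():
    """Deterministic strongly coupled 4-gene chain dataset."""
    from mrmsn.synthetic import SimulationSpec, simulate

    return simulate(SimulationSpec(n=4, m=200, seed=7))
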