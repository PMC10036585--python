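import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("suite", deadline=None, derandomize=True)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(20230310)


@pytest.fixture
def two_clique_stack():
    """Two disconnected 3-cliques replicated identically in 3 layers."""
    from oracles import make_stack
    C = np.zeros((6, 6))
    C[:3, :3] = 1.0
    C[3:, 3:] = 1.0
    np.fill_diagonal(C, 0.0)
    return make_stack([C] * 3)
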