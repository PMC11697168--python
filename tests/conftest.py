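import numpy as np
import pytest

from tunneltraffic import SimConfig, build_network
from tunneltraffic.network import BranchProbabilities


@pytest.fixture
def mini_net():
    """20-cell main tunnel, 8-cell loop: every invariant at toy scale."""
    return build_network(1, main_length=20, loop_length=8)


@pytest.fixture
def default_net():
    return build_network(2)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def mini_config(**kw):
    """Small, fast simulation config on the miniature network."""
    base = dict(
        delta=1,
        main_length=20,
        loop_length=8,
        probs=BranchProbabilities(0.2, 0.2, 0.2, 0.2),
        n0=10,
        T=200,
        seed=0,
        window=(150, 200),
    )
    base.update(kw)
    return SimConfig(**base)
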