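import numpy as np
import pytest

from senesim import CellState, KineticParams, StrategyParams


@pytest.fixture
def kp() -> KineticParams:
    return KineticParams()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260919)


@pytest.fixture
def fr() -> StrategyParams:
    return StrategyParams(alpha=0.0, repair_mode="fixed")


@pytest.fixture
def random_cell_factory(rng):
    """Cells with random positive pools, biased toward moderate damage."""

    def make(**kw):
        pools = rng.uniform(1.0, 200.0, size=4)
        pools[2:] *= rng.uniform(0.0, 0.6)  # damage usually below half
        return CellState(
            P_ga=pools[0], P_ra=pools[1], P_gd=pools[2], P_rd=pools[3],
            mu_net_prev=rng.uniform(0.0, 0.6), **kw,
        )

    return make
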