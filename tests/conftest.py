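import numpy as np
import pytest

from isletcycle import (
    default_initial_state,
    default_parameters,
    run_scenario,
)
from isletcycle.simulate import builtin_scenario, integrate


def cell_cycle_matrix(G, p):
    """Constant-coefficient matrix of the frozen-glucose cell-cycle block."""
    tr = p.p1 * (1.0 + p.p5 * G)
    return np.array(
        [[-(tr + p.p4), 0.0, 2.0 * p.p3],
         [tr, -p.p2, 0.0],
         [0.0, p.p2, -p.p3]]
    )


@pytest.fixture(scope="session")
def params():
    return default_parameters()

@pytest.fixture(scope="session")
def init():
    return default_initial_state()


@pytest.fixture(scope="session")
def phys_traj():
    """Physiological scenario: defaults, 120 min, 1-min output grid."""
    return run_scenario("physiological")


@pytest.fixture(scope="session")
def infusion_traj():
    """Glucose infusion: p6 -> 8.6806, 96 h."""
    return run_scenario("infusion")


@pytest.fixture(scope="session")
def type2_traj():
    return run_scenario("type2")


@pytest.fixture(scope="session")
def type1_traj():
    return run_scenario("type1")


@pytest.fixture(scope="session")
def long_traj_1e5(params, init):
    """Physiological conditions extended to 1e5 minutes (100-min grid)."""
    scen = builtin_scenario("physiological")
    return integrate(scen.resolve(params), init, 1e5, output_dt_min=100.0)
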