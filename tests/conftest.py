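import numpy as np
import pytest

import thermocrm as tc


@pytest.fixture(scope="session")
def cell():
    return tc.CellParameters()


@pytest.fixture(scope="session")
def small_network():
    return tc.build_network(5, 1.0e6)


@pytest.fixture(scope="session")
def headline_scaled_config():
    """Desk-scale analogue of the headline assembly regime: reversible
    kinetics with the 25-metabolite hierarchy's per-step free-energy drop
    (5.0e6/24 J mol^-1 per level) on a 10-metabolite network."""
    step = 5.0e6 / 24
    return tc.RegimeConfig(M=10, B=50, delta_G_total=step * 9,
                           kinetics_mode="reversible", seed=0)


@pytest.fixture(scope="session")
def syntrophy_run():
    com = tc.make_fixture("syntrophy_demo")
    traj = tc.integrate(com)
    state, report = tc.steady_state(traj, com)
    return com, traj, state, report


@pytest.fixture(scope="session")
def pollution_run():
    com = tc.make_fixture("pollution_demo")
    traj = tc.integrate(com)
    state, report = tc.steady_state(traj, com)
    return com, traj, state, report


@pytest.fixture(scope="session")
def small_assembly_run():
    """One complete random assembly at desk scale, reused across tests."""
    step = 5.0e6 / 24
    cfg = tc.RegimeConfig(M=8, B=20, delta_G_total=step * 7,
                          kinetics_mode="reversible", seed=125)
    com = tc.generate_community(None, cfg, seed=125)
    traj = tc.integrate(com)
    state, report = tc.steady_state(traj, com)
    return com, traj, state, report
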