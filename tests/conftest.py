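import logging

import numpy as np
import pytest

import shoal

logging.getLogger("shoal").setLevel(logging.WARNING)


@pytest.fixture(scope="session")
def sim3_long():
    """Long reference run of three fish at the default parameters."""
    cfg = shoal.SimulationConfig(n_fish=3, n_steps=500_000, seed=1)
    traj = shoal.simulate(cfg)
    vel = shoal.estimate_velocities(traj)
    series = shoal.order_parameters(traj, vel)
    return traj, vel, series


@pytest.fixture(scope="session")
def sim20():
    """Reference run of twenty fish at the default parameters."""
    cfg = shoal.SimulationConfig(n_fish=20, n_steps=100_000, seed=2)
    traj = shoal.simulate(cfg)
    return traj


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
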