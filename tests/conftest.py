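import logging

import numpy as np
import pytest

from gbmsim.config import SimulationConfig

logging.getLogger("gbmsim").setLevel(logging.ERROR)


def small_sim_config(seed: int = 7) -> SimulationConfig:
    """Desk-size study conditions for behavioral tests: 10x10 low-res lattice,
    small tumor, gentle field so a coarser ODE micro-step stays accurate."""
    cfg = SimulationConfig()
    cfg.lattice.shape = (60, 60)
    cfg.tumor_seed.radius = 3
    cfg.field_init.amplitude_nM = 100.0
    cfg.ode.dt_s = 0.25
    cfg.steps = 20
    cfg.replicates = 1
    cfg.seed = seed
    return cfg


@pytest.fixture
def small_config() -> SimulationConfig:
    return small_sim_config()


@pytest.fixture(scope="session")
def small_run():
    """One 20-step small simulation shared by read-only behavioral tests."""
    from gbmsim.engine import Simulation

    sim = Simulation(small_sim_config(), seed=7)
    sim.run_steps(20)
    return sim


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
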