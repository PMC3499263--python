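import numpy as np
import pytest

from ncdsbm import (ToyDualBasinSpec, build_toy_topology, run_simulation,
                    SimulationParams)


@pytest.fixture(scope="session")
def toy_spec():
    return ToyDualBasinSpec()


@pytest.fixture(scope="session")
def toy_system(toy_spec):
    """(topology, conformer A, conformer B) for the default toy spec."""
    return build_toy_topology(toy_spec)


@pytest.fixture(scope="session")
def short_trajectory(toy_system):
    """A short thermal trajectory of the toy chain (seeded)."""
    top, a, _ = toy_system
    params = SimulationParams(n_steps=20_000, save_interval=200, seed=11)
    return run_simulation(top, a, params)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
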