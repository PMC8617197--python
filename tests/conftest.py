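import numpy as np
import pytest

from bcellflow.simulate import SimConfig, simulate_cite


@pytest.fixture(scope="session")
def default_sim():
    """One default-configuration simulation shared across tests."""
    return simulate_cite(SimConfig(seed=0))


@pytest.fixture(scope="session")
def noncycling_sim():
    """A quiescent-only, doublet-free simulation: a clean linear trajectory."""
    cfg = SimConfig(phase_props={"G0G1": 1.0}, doublet_rate=0.0, seed=0)
    return simulate_cite(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
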