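import numpy as np
import pytest

import fretlines as fl


@pytest.fixture(scope="session")
def ctx():
    """Reference dye pair: R0 = 50 Å, tauD0 = 4 ns."""
    return fl.FretContext(R0=50.0, tauD0=4.0)


@pytest.fixture(scope="session")
def ctx_pa():
    """Same dye pair with an acceptor quantum yield (proximity-ratio work)."""
    return fl.FretContext(R0=50.0, tauD0=4.0, phiF_D=0.8, phiF_A=0.8)


@pytest.fixture(scope="session")
def donor_mix():
    """Two-state donor: 4 ns / 1 ns at fractions 0.25 / 0.75, yields 0.8 / 0.2."""
    return fl.DonorMixture([4.0, 1.0], [0.25, 0.75], [0.8, 0.2])


@pytest.fixture(scope="session")
def two_state_sim(ctx):
    """Two-state exchange experiment: E = 0.25/0.80, k12 = k21 = 1/ms,
    0.5 ms mean bursts at 100 photons/ms, 2000 bursts.

    Session-scoped: several tests and acceptance checks share it.
    """
    model = fl.two_state_model(0.25, 0.8, 1.0, 1.0)
    config = fl.SimulationConfig(
        count_rate=100.0, burst_mean_ms=0.5, n_bursts=2000, min_photons=50, seed=11
    )
    table = fl.simulate_experiment(model, config, ctx)
    obs = fl.analyze_bursts(table, ctx)
    return model, table, obs


@pytest.fixture(scope="session")
def static_sim(ctx):
    """Single-state (static) experiment at E = 0.25."""
    model = fl.KineticModel([fl.FretState("s", E=0.25)], np.zeros((1, 1)))
    config = fl.SimulationConfig(n_bursts=600, seed=4)
    table = fl.simulate_experiment(model, config, ctx)
    obs = fl.analyze_bursts(table, ctx)
    return table, obs
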