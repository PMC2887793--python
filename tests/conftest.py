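import networkx as nx
import numpy as np
import pytest

from netsync import (
    PhaseRecord,
    SimulationConfig,
    draw_initial_configuration,
    generate_ba,
    integrate,
    wrap_phase,
)


@pytest.fixture(scope="session")
def ba_small() -> nx.Graph:
    return generate_ba(64, 2, 7)


@pytest.fixture(scope="session")
def ba_512() -> nx.Graph:
    return generate_ba(512, 2, 11)


def make_record(phases: np.ndarray, dt_eff: float = 0.1) -> PhaseRecord:
    """Wrap an explicit (T, N) phase array into a PhaseRecord."""
    phases = np.asarray(phases, dtype=np.float64)
    times = dt_eff * np.arange(1, phases.shape[0] + 1)
    return PhaseRecord(
        times=times, phases=wrap_phase(phases), unwrapped=phases, provenance={}
    )


@pytest.fixture(scope="session")
def short_run(ba_small):
    """One short noisy simulation reused by several observable tests."""
    init = draw_initial_configuration(64, 5)
    cfg = SimulationConfig(
        coupling=0.05, t_transient=20.0, t_measure=50.0, rng_seed=5
    )
    return ba_small, cfg, init, integrate(ba_small, cfg, init)
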