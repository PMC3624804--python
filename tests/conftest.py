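import numpy as np
import pytest

from spedre import (
    TimeSeriesDataset,
    generate_dataset,
    make_ring_scenario,
    parse_network,
    simulate,
)

AB_MODEL = "A -> B ; k1\nB -> A ; k2\n"


@pytest.fixture
def ab_network():
    return parse_network(AB_MODEL)


@pytest.fixture
def ab_problem(ab_network):
    """Noise-free A<->B data simulated at known mid-bin rates (k1=0.3, k2=0.7)."""
    params = np.array([0.3, 0.7])
    t = np.linspace(0.0, 4.0, 11)
    traj = simulate(ab_network, params, np.array([1.0, 0.2]), t)
    dataset = TimeSeriesDataset.from_trajectories(ab_network.species_names, [traj])
    return ab_network, params, dataset


@pytest.fixture(scope="session")
def ring10_problem():
    """The canonical ring(10) recovery problem: noise-free, truth at bin midpoints."""
    scenario, scheme = make_ring_scenario(10, seed=0)
    dataset = generate_dataset(scenario)
    return scenario, scheme, dataset
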