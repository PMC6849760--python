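import numpy as np
import pytest

from phytoscale.inference import fit_mst
from phytoscale.simulate import (
    DEFAULT_CR_PARAMS,
    DEFAULT_GPP_PARAMS,
    SimulationConfig,
    simulate_experiment,
)

TRUTH_GPP = DEFAULT_GPP_PARAMS
TRUTH_CR = DEFAULT_CR_PARAMS


@pytest.fixture(scope="session")
def noise_free_communities():
    config = SimulationConfig(n_cells=200, noise_sd=0.0, abundance_noise_sd=0.0, seed=11)
    communities, _ = simulate_experiment(config)
    return communities


@pytest.fixture(scope="session")
def noisy_communities():
    config = SimulationConfig(n_cells=200, noise_sd=0.3, abundance_noise_sd=0.15, seed=19)
    communities, _ = simulate_experiment(config)
    return communities


@pytest.fixture(scope="session")
def noise_free_gpp_fit(noise_free_communities):
    return fit_mst(noise_free_communities, "gpp", n_starts=15, seed=0, compute_ci=False)


@pytest.fixture(scope="session")
def noisy_gpp_fit(noisy_communities):
    return fit_mst(noisy_communities, "gpp", n_starts=15, seed=0, compute_ci=False)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
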