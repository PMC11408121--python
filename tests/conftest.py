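import numpy as np
import pytest

from bandcorr.inference import MCMCConfig
from bandcorr.study import run_study
from bandcorr.synthetic_data import SimulationConfig, simulate_marray


@pytest.fixture(scope="session")
def default_study():
    """One scaled-down replication study at the standard data scale.

    100 replicates of T=36 years x 10,000 releases/year, both prior
    families fit to each m-array with the desk MCMC profile.  Shared across
    the acceptance-style checks because it is by far the most expensive
    fixture (~3 minutes).
    """
    records, summary = run_study(
        SimulationConfig(), None, MCMCConfig.desk(), n_sims=100, base_seed=1
    )
    return records, summary


@pytest.fixture(scope="session")
def small_replicate():
    """A small (T=8, 500 releases/yr) m-array plus its truth, for fast fits."""
    config = SimulationConfig(T=8, releases=500)
    rng = np.random.default_rng(42)
    marray, truth = simulate_marray(config, rng)
    return config, marray, truth


@pytest.fixture(scope="session")
def default_replicate():
    """One full-scale (T=36, 10k releases/yr) replicate."""
    config = SimulationConfig()
    rng = np.random.default_rng(7)
    marray, truth = simulate_marray(config, rng)
    return config, marray, truth
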