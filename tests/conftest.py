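import logging

import numpy as np
import pytest

from qsoc.calibrate import MCMCConfig, run_mcmc
from qsoc.synthetic import generate_dataset

logging.disable(logging.WARNING)  # silence the PET-fallback notice in bulk runs


@pytest.fixture(scope="session")
def network4():
    """Canonical four-site synthetic network: 40 annual observations over
    40 years, noise sd 1.5 Mg C/ha, true u0=0.05, eta11=0.36 shared and
    q0 in {0.9, 1.0, 1.15, 1.3}."""
    profiles, datasets, climate = generate_dataset(
        n_sites=4, seed=1, n_obs=40, duration=40
    )
    return profiles, datasets, climate


@pytest.fixture(scope="session")
def calib_chains(network4):
    """Reference hierarchical calibration of the four-site network
    (4 chains x 20 000, 5 000 burn-in, seed 1)."""
    _, datasets, _ = network4
    cfg = MCMCConfig(n_chains=4, n_iter=20_000, burn_in=5_000, seed=1)
    return run_mcmc(datasets, cfg)


@pytest.fixture(scope="session")
def quick_chains(network4):
    """Short calibration for structural/projection tests (2 chains x 3 000)."""
    _, datasets, _ = network4
    cfg = MCMCConfig(n_chains=2, n_iter=3_000, burn_in=1_000, seed=11)
    return run_mcmc(datasets, cfg)
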