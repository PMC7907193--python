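"""Shared fixtures: small seeded synthetic studies and a reusable model fit.

Everything is generated at test time; expensive objects are session-scoped
so the model is fitted once and inspected by several tests.
"""

import numpy as np
import pytest

from fearscape.stmodel import Hyperparameters, McmcSettings, fit
from fearscape.synthetic import generate_landscape, simulate_dataset, simulate_study


@pytest.fixture(scope="session")
def small_landscape():
    return generate_landscape(seed=11, n_sites=12, extent_m=4000.0)


@pytest.fixture(scope="session")
def study():
    """Full end-to-end synthetic study at the real survey's design size."""
    return simulate_study(7, missing_frac=0.1)


@pytest.fixture(scope="session")
def recovery_fit():
    """One moderate-length fit of a known-truth dataset, reused across tests."""
    data, truth = simulate_dataset(
        seed=5, n_sites=21, T=24, beta=(0.5, -0.3), n_null_covariates=2,
        missing_frac=0.1,
    )
    result = fit(data, mcmc=McmcSettings(iterations=1500, burnin=500, thin=2, seed=5))
    return data, truth, result


@pytest.fixture
def rng():
    return np.random.default_rng(42)
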