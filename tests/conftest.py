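import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import coexdiff as cd

settings.register_profile(
    "ci", derandomize=True, max_examples=50, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_params() -> cd.SimParams:
    """A fast two-cohort world: 300 genes, 5 planted modules, 20+30 samples."""
    return cd.SimParams(
        n_genes=300,
        n_modules=5,
        module_size=20,
        n_early=20,
        n_late=30,
        de_fraction=0.1,
        de_log2fc=2.0,
        n_true_terms=5,
        n_decoy_terms=20,
        n_perturbed_sets=1,
        seed=123,
    )


@pytest.fixture(scope="session")
def small_world(small_params):
    truth = cd.simulate_truth(small_params)
    design = cd.simulate_design(small_params)
    counts = cd.CountMatrix(cd.simulate_counts(truth, design, small_params), design)
    return truth, design, counts


@pytest.fixture(scope="session")
def balanced_design():
    return cd.assign_cohorts([60.0] * 25 + [80.0] * 25)


def nb_counts(rng, mu, phi, shape):
    """Independent NB draws with mean mu and dispersion phi."""
    if phi == 0:
        return rng.poisson(mu, size=shape)
    r = 1.0 / phi
    return rng.negative_binomial(r, r / (r + mu), size=shape)
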