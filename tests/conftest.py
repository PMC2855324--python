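import numpy as np
import pytest

from admixscan.cohort import SimParams, simulate_cohort, simulate_phenotypes
from admixscan.panel import generate_aim_panel


@pytest.fixture(scope="session")
def small_panel():
    """Two chromosomes, 60 AIMs, 2 Mb spacing."""
    return generate_aim_panel(60, 2, 0.75, seed=101)


@pytest.fixture(scope="session")
def small_cohort(small_panel):
    params = SimParams(n_individuals=60, seed=102)
    return simulate_phenotypes(simulate_cohort(small_panel, params), params)


@pytest.fixture(scope="session")
def recovery_mcmc():
    """MCMC run on a cohort with known theta=0.8, lambda=6 (shared by several tests)."""
    from admixscan.hmm import mcmc_fit

    panel = generate_aim_panel(300, 3, 0.75, seed=11)
    params = SimParams(n_individuals=200, theta_mean=0.8, theta_sd=0.0, lambda_gen=6.0, seed=12)
    cohort = simulate_cohort(panel, params)
    post = mcmc_fit(cohort.genotypes, panel, seed=13)
    return panel, cohort, post
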