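import warnings

import pytest

from ppfbayes import (
    GENETIC_FEATURES,
    NUMERIC_FEATURES,
    SamplerConfig,
    augment_pairwise_products,
    make_study_like_cohort,
    zscore_normalize,
)

# non-convergence warnings from deliberately tiny sampler budgets are noise here
warnings.filterwarnings("ignore", message="posterior for")


@pytest.fixture(scope="session")
def study_cohort():
    """Study-like synthetic cohort: 39 rows, 19 PPF / 20 nPPF, 23 missing."""
    return make_study_like_cohort(seed=11)


@pytest.fixture(scope="session")
def augmented_study(study_cohort):
    """Z-scored study cohort with the six derived biomarker products."""
    normalized, transform = zscore_normalize(study_cohort, list(NUMERIC_FEATURES))
    table = augment_pairwise_products(normalized, list(GENETIC_FEATURES), include_self=True)
    return table, transform


@pytest.fixture()
def laplace_sampler():
    """Deterministic Laplace-approximation sampler for fast unit tests."""
    return SamplerConfig(n_chains=2, n_draws=500, n_warmup=0, seed=7, algorithm="laplace")


@pytest.fixture()
def mcmc_sampler():
    """Moderate-budget MCMC sampler used where real posterior draws matter."""
    return SamplerConfig(n_chains=4, n_draws=500, n_warmup=300, seed=7, algorithm="mcmc")
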