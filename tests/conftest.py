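import numpy as np
import pytest

from civdwave.detect import phenotype_table
from civdwave.synth import (
    GenotypeSimSpec,
    SignalParams,
    simulate_cohort,
    simulate_genotypes,
)


@pytest.fixture(scope="session")
def noiseless_params():
    return SignalParams(noise_sd=0.0, temp_noise_sd=0.0)


@pytest.fixture(scope="session")
def small_cohort(noiseless_params):
    """10 noiseless subjects, 3 without CIVD, with their truth ledger."""
    recs, truth = simulate_cohort(10, prevalence=0.7, params=noiseless_params, seed=11)
    return recs, truth


@pytest.fixture(scope="session")
def small_phenotypes(small_cohort):
    recs, _ = small_cohort
    return phenotype_table(recs)


@pytest.fixture(scope="session")
def genotypes_200x50():
    return simulate_genotypes(
        GenotypeSimSpec(n_subjects=200, n_variants=50, maf_range=(0.1, 0.5), seed=3)
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
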