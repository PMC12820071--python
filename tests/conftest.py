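"""Shared fixtures: a small synthetic cohort reused across module tests."""

import numpy as np
import pytest

from adloe import phenotyping, simulate


@pytest.fixture(scope="session")
def small_config():
    return simulate.default_config(
        seed=11, n_individuals=1500, n_snps=60,
        n_shared=4, n_ad_only=2, n_loe_only=2,
        base_prevalence={"ad": 0.08, "loe": 0.10})


@pytest.fixture(scope="session")
def small_cohort(small_config):
    """(genotypes, annotation, cohort, truth, encounters) at zero noise."""
    genos, ann = simulate.simulate_genotypes(small_config)
    cohort, truth = simulate.simulate_phenotypes(genos, small_config)
    enc = simulate.simulate_encounters(cohort, phenotyping.PhecodeMap.default(),
                                       small_config)
    return genos, ann, cohort, truth, enc


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
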