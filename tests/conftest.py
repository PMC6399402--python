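"""Shared fixtures: small synthetic cohorts generated at test time."""

import numpy as np
import pytest

from raregene.synthcohort import CohortSpec, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """1,200-sample single-population cohort, 12 genes, light missingness."""
    spec = CohortSpec(
        n_cases=600,
        n_controls=600,
        n_genes=12,
        variants_per_gene=(10, 20),
        missing_rate=0.01,
        seed=42,
    )
    return simulate_cohort(spec)


@pytest.fixture(scope="session")
def stratified_cohort():
    """Two-subpopulation cohort with case-control confounding."""
    spec = CohortSpec(
        n_cases=300,
        n_controls=300,
        n_subpops=2,
        fst=0.05,
        subpop_mixing=np.array([[0.7, 0.3], [0.3, 0.7]]),
        n_genes=40,
        variants_per_gene=(10, 20),
        sfs_weights=(0.10, 0.0, 0.45, 0.45),
        seed=7,
    )
    return simulate_cohort(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
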