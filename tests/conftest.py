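import numpy as np
import pytest

from brainstates import (
    CohortConfig,
    concatenate,
    fit_pca,
    make_ground_truth,
    project,
    simulate_cohort,
    standardize,
)


@pytest.fixture(scope="session")
def small_cohort():
    """3-state, 10-subject cohort with well-separated states."""
    cfg = CohortConfig(n_per_group=5, T=150, R=20, n_states=3, seed=7)
    truth = make_ground_truth(cfg)
    cohort = simulate_cohort(truth, cfg)
    return cfg, truth, cohort


@pytest.fixture(scope="session")
def small_projected(small_cohort):
    """Standardized, concatenated, PCA-projected version of the small cohort."""
    _, truth, cohort = small_cohort
    stacked, spans = concatenate([standardize(s) for s in cohort.subjects])
    pca = fit_pca(stacked)
    return project(stacked, pca), [b - a for a, b in spans], pca


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
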