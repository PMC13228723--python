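"""Shared fixtures: reference assets and cohorts are expensive to build, so
they are session-scoped and reused across test modules."""

import warnings

import numpy as np
import pytest

from bscore3d import (
    CohortConfig,
    build_reference_assets,
    generate_cohort,
    make_template,
)

# B-scores near the band edges are expected in synthetic extremes; keep the
# suite quiet about the sanity warning
warnings.filterwarnings("ignore", message="B-score .* outside the typical")


@pytest.fixture(scope="session")
def train_config():
    return CohortConfig(n_subjects=150, seed=101, sigma_mr=0.0, sigma_ct=0.0)


@pytest.fixture(scope="session")
def train_cohort(train_config):
    """Truth shapes only — training and truth-score checks need no
    observations."""
    return generate_cohort(train_config, with_observations=False)


@pytest.fixture(scope="session")
def reference_assets(train_config, train_cohort):
    """(model, scale) trained on a noise-free 150-subject cohort."""
    return build_reference_assets(train_config, cohort=train_cohort)


@pytest.fixture(scope="session")
def clean_cohort():
    """Small noise-free evaluation cohort (alien CT parameterization)."""
    return generate_cohort(
        CohortConfig(n_subjects=10, seed=202, sigma_mr=0.0, sigma_ct=0.0)
    )


@pytest.fixture(scope="session")
def template():
    return make_template(3)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
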