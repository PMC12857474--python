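import warnings

import numpy as np
import pytest
from hypothesis import settings

from plirisk import SimConfig, run_pipeline, simulate_cohort

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=60)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_cohort():
    """Moderate synthetic cohort shared across test modules."""
    return simulate_cohort(SimConfig(n_persons=12_000, seed=42))


@pytest.fixture(scope="session")
def pipeline_result(small_cohort):
    """Full pipeline run on the shared cohort (complete mode, logit)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return run_pipeline(small_cohort, seed=0)


@pytest.fixture(scope="session")
def big_truth():
    """Truth table of a large default-config cohort, for marginal-rate checks."""
    cohort = simulate_cohort(SimConfig(n_persons=200_000, seed=20))
    return cohort.config, cohort.truth
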