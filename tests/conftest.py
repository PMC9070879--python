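import warnings

import pytest

from strendo.se_models import fit_se_model
from strendo.synthetic_data import generate_cohort, study_config

# fixed seeds for the simulated study cohorts used across the suite
COHORT_SEED = 101
FIT_SEED = 7


@pytest.fixture(scope="session")
def lin_cohort():
    """One synthetic cohort at the default (study-calibrated) conditions."""
    return generate_cohort(study_config("lin", seed=COHORT_SEED))


@pytest.fixture(scope="session")
def lin_fit(lin_cohort):
    """Full-quality hierarchical Lin fit on the default cohort (shared: slow)."""
    ds, _ = lin_cohort
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return fit_se_model(ds, "lin", seed=FIT_SEED)
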