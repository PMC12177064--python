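import numpy as np
import pytest

from mica import preprocess, synthio


@pytest.fixture(scope="session")
def fixture_cohort():
    """The canonical synthetic cohort (seed 0): raw tables."""
    cfg = synthio.fixture_config(seed=0)
    table, cohort = synthio.simulate_cohort(cfg)
    return cfg, table, cohort


@pytest.fixture(scope="session")
def analysis_ready(fixture_cohort):
    """Canonical cohort after the standard preprocessing chain."""
    cfg, table, cohort = fixture_cohort
    filtered = preprocess.prevalence_filter(table)
    complete = preprocess.pmm_impute(cohort, seed=11)
    complete = preprocess.add_transformed_outcome(complete)
    return cfg, filtered, complete


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
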