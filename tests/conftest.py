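import numpy as np
import pytest

import connage as ca


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_cohort():
    """40 subjects, 12 regions, 120 timepoints — enough for every stage."""
    cfg = ca.CohortConfig(
        n_subjects=40, n_regions=12, n_timepoints=120, seed=7, signal_strength=0.7
    )
    return ca.generate_cohort(cfg)


@pytest.fixture(scope="session")
def cohort_dir(small_cohort, tmp_path_factory):
    d = tmp_path_factory.mktemp("cohort")
    ca.write_cohort(small_cohort, d)
    return d
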