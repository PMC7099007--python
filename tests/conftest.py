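import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import phenofactor as pf

settings.register_profile("ci", deadline=None, max_examples=40, derandomize=True)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_cohort():
    """A fast 120-subject cohort with clear planted structure."""
    cfg = pf.SyntheticConfig(n_subjects=120, n_regions=15, n_tasks=10,
                             r_true=3, noise_sd=0.05, label_separation=1.5, seed=3)
    m, x, cohort, truth = pf.generate(cfg)
    return m, x, cohort, truth


@pytest.fixture
def random_cohort_table(rng):
    """Cohort metadata with labels independent of everything else."""
    def make(n, seed=0):
        r = np.random.default_rng(seed)
        return pf.CohortTable(pd.DataFrame({
            "subject_id": [f"s{i:03d}" for i in range(n)],
            "label": r.permutation(np.repeat(["AD", "MCI", "CN"],
                                             [n - 2 * (n // 3), n // 3, n // 3])),
            "interval_years": r.gamma(4.0, 0.5, n),
            "sex": r.integers(0, 2, n).astype(float),
            "age": r.normal(73, 7, n),
        }))
    return make
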