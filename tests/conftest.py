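import numpy as np
import pandas as pd
import pytest

import twinlate as tl


@pytest.fixture(scope="session")
def default_cohort():
    """A moderate cohort under the default (ordinal) generating conditions."""
    cfg = tl.SimConfig(n_pairs_mz=120, n_pairs_dz=180, seed=7042)
    cohort, truth = tl.simulate_cohort(cfg)
    return cfg, cohort, truth


@pytest.fixture(scope="session")
def continuous_cohort():
    """Continuous-measurement cohort for estimator-recovery checks."""
    cfg = tl.SimConfig(
        n_pairs_mz=500,
        n_pairs_dz=500,
        seed=1234,
        ordinal=False,
        var_a=(0.3, 0.02, 0.003),
        var_c=(0.2, 0.015, 0.002),
        var_e=(0.4, 0.03, 0.005),
        cov_is=(0.0, 0.0, 0.0),
    )
    cohort, truth = tl.simulate_cohort(cfg)
    return cfg, cohort, truth


def make_cohort(individual_rows, observation_rows):
    """Build a TwinCohort from plain tuples (test helper)."""
    ind = pd.DataFrame(
        individual_rows,
        columns=["person_id", "family_id", "zygosity", "study", "sex",
                 "birth_year", "education", "isei", "illness", "apoe_e4",
                 "dementia", "event_age"],
    ).astype({"apoe_e4": "Int64", "birth_year": "Int64", "education": "Int64"})
    obs = pd.DataFrame(
        observation_rows, columns=["person_id", "wave", "age_at_wave", "score"]
    ).astype({"score": "Float64"})
    return tl.TwinCohort(ind, obs)


@pytest.fixture
def toy_cohort():
    """2 pairs x 2 twins x 3 waves, fully observed."""
    ind, obs = [], []
    for f, (zyg, study) in enumerate([("MZ", "SATSA"), ("DZ", "OCTO")], start=1):
        for i in range(2):
            pid = f"P{f}{i}"
            ind.append((pid, f"F{f}", zyg, study, "F", 1920, 2, 45.0, 2.0,
                        1, i % 2, 85.0))
            for w in range(1, 4):
                obs.append((pid, w, 70.0 + 3 * w, (w + i) % 4))
    return make_cohort(ind, obs)
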