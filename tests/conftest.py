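import numpy as np
import pytest
from hypothesis import settings, HealthCheck

import emrfrailty as ef

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_cohort():
    """A 60-patient cohort, enough to exercise every table."""
    cfg = ef.SimConfig(n_physicians=6, patients_per_physician=10, seed=7)
    tables, assessments = ef.generate_cohort(cfg)
    return cfg, tables, assessments


@pytest.fixture(scope="session")
def study_cohort():
    """A full-size cohort under the default study conditions (52 x 15,
    prevalence 0.177, the four default planted signals)."""
    cfg = ef.SimConfig(seed=1)
    tables, assessments = ef.generate_cohort(cfg)
    labels = ef.dichotomize(assessments)
    fm = ef.build_feature_matrix(tables, labels)
    y = labels.labels.reindex(fm.X.index).to_numpy()
    return cfg, tables, labels, fm, y


@pytest.fixture(scope="session")
def noise_matrix():
    """A pure-noise binary matrix with balanced-ish labels."""
    rng = np.random.default_rng(123)
    X = rng.integers(0, 2, size=(120, 25)).astype(float)
    y = (rng.random(120) < 0.3).astype(int)
    return X, y
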