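import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import gcresponse as g
from gcresponse.synthetic import CohortConfig

settings.register_profile(
    "ci", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow], deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def cohort_small():
    """40-sample synthetic cohort shared by read-only tests."""
    return g.simulate_cohort(CohortConfig(n_samples=40), seed=11)


@pytest.fixture(scope="session")
def cohort_default():
    """Default 65-sample cohort (the study conditions)."""
    return g.simulate_cohort(seed=7)


@pytest.fixture(scope="session")
def cells_default():
    return g.simulate_single_cells(seed=3)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def toy_feature_matrix(seed=0, n=120, informative=3, noise=20, effect=1.2):
    """Labelled Gaussian features: `informative` columns carry a class shift."""
    from gcresponse.response import (FeatureMatrix, NEGATIVE_LABEL,
                                     POSITIVE_LABEL)

    r = np.random.default_rng(seed)
    y = r.random(n) < 0.5
    cols = {}
    for i in range(informative):
        cols[f"inf_{i}"] = r.normal(0, 1, n) + effect * y
    for i in range(noise):
        cols[f"noise_{i}"] = r.normal(0, 1, n)
    X = pd.DataFrame(cols, index=[f"s{i}" for i in range(n)])
    ys = pd.Series(np.where(y, POSITIVE_LABEL, NEGATIVE_LABEL), index=X.index,
                   name="label")
    return FeatureMatrix(X=X, y=ys)
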