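import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import gancova as g

settings.register_profile("repeatable", derandomize=True, deadline=None)
settings.load_profile("repeatable")


@pytest.fixture(scope="session")
def pca1_truth():
    """Shipped PCA1-like single-response scenario (calibrated once)."""
    return g.pca1_like_truth()


@pytest.fixture(scope="session")
def panel_truth():
    """Shipped 12-locus panel scenario (calibrated once)."""
    return g.default_truth()


@pytest.fixture(scope="session")
def cohort185(pca1_truth):
    """One 185-subject draw of the PCA1-like scenario plus its response."""
    cohort, panel = g.generate_cohort(pca1_truth, 185, seed=0)
    y = panel.values["PCA1like"].to_numpy()
    return cohort, y


def random_cohort_frame(rng, n=60, covariates=("age", "PF", "Se", "vitD")):
    """A small ad-hoc subject frame with standard-normal covariates."""
    n_male = n // 2
    sex = np.array(["male"] * n_male + ["female"] * (n - n_male))
    sex = sex[rng.permutation(n)]
    data = {"sex": sex}
    for name in covariates:
        data[name] = rng.normal(size=n)
    return pd.DataFrame(data, index=[f"S{i}" for i in range(n)])
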