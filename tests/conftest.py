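import numpy as np
import pytest

import vitaldrift as vd


@pytest.fixture(scope="session")
def small_params():
    """A reduced cohort used by fast unit tests."""
    return vd.SyntheticParams(n_normal=20, n_abnormal=5, seed=42)


@pytest.fixture(scope="session")
def small_cohort(small_params):
    return vd.generate_cohort(small_params)


@pytest.fixture(scope="session")
def default_cohort():
    """The study-scale cohort (154 normal / 17 abnormal) at a fixed seed."""
    return vd.preprocess(vd.generate_cohort(vd.SyntheticParams(seed=1)))


@pytest.fixture(scope="session")
def default_split(default_cohort):
    return vd.split_by_outcome(default_cohort)


@pytest.fixture(scope="session")
def default_model(default_cohort, default_split):
    """Normalisation, fitted model of normality and threshold for the default cohort."""
    normal, _ = default_split
    params = vd.fit_normalization(default_cohort)
    model = vd.NormalityModel.fit(normal, params)
    threshold = vd.compute_threshold(model, normal, params)
    return params, model, threshold


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
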