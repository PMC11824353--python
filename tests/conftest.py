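import warnings

import numpy as np
import pytest

from sigspec.synthetic import CancerProfile, make_reference_signatures, simulate_cohort


@pytest.fixture(scope="session")
def small_signatures():
    return make_reference_signatures(5, sparsity_concentration=0.1, seed=11)


@pytest.fixture(scope="session")
def small_cohort(small_signatures):
    """Two cancer types x 12 patients, modest burdens; with ground truth."""
    profiles = [
        CancerProfile("AAA", np.array([0.9, 0.6, 0.1, 0.1, 0.1]), n_mut_mean=500),
        CancerProfile("BBB", np.array([0.1, 0.1, 0.6, 0.6, 0.6]), n_mut_mean=500),
    ]
    return simulate_cohort(profiles, small_signatures, 12, seed=7)


@pytest.fixture(autouse=True)
def _quiet_convergence():
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*did not converge.*")
        warnings.filterwarnings("ignore", category=FutureWarning)
        yield


@pytest.fixture
def separable_table():
    """A linearly separable binary task: feature f0 alone decides the label."""
    from sigspec.ml import FeatureTable

    rng = np.random.default_rng(42)
    n = 300
    X = rng.normal(size=(n, 6))
    y = (rng.random(n) < 0.3).astype(int)
    X[:, 0] = y * 2.0 - 1.0 + rng.normal(0, 0.1, n)
    return FeatureTable(X, y, [f"s{i}" for i in range(n)], [f"f{i}" for i in range(6)])
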