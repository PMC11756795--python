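import numpy as np
import pytest

from transptlr import Dataset, EMConfig, SimulationConfig, gen_multidata


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def small_data():
    """n=40, p=6 Gaussian design with a sparse signal and t5 noise."""
    rng = np.random.default_rng(7)
    X = rng.standard_normal((40, 6))
    beta = np.array([1.0, -0.8, 0.0, 0.5, 0.0, 0.0])
    y = X @ beta + 0.5 * rng.standard_t(5, 40)
    return Dataset(X, y), beta


@pytest.fixture()
def medium_t_data():
    """n=200, p=12 design with t5 errors for EM behaviour checks."""
    rng = np.random.default_rng(21)
    X = rng.standard_normal((200, 12))
    beta = np.zeros(12)
    beta[:4] = [1.0, -1.5, 0.7, 0.4]
    y = X @ beta + rng.standard_t(5, 200)
    return Dataset(X, y), beta


@pytest.fixture(scope="session")
def study_instance():
    """One replication of the main simulation design (t5 errors, all
    sources transferable) shared across transfer tests."""
    cfg = SimulationConfig(error_family="t", seed=5, n_transferable=10)
    return gen_multidata(cfg)


@pytest.fixture()
def fast_em():
    return EMConfig(n_lambda=12, lambda_min_ratio=0.02, cv_tol=1e-3,
                    cv_max_iter=40, tol=1e-5, max_iter=200)
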