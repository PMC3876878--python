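import numpy as np
import pytest

from coxshoot import SurvivalDataset


def make_exp_cox_data(seed: int, n: int, beta, censor_scale: float | None = 2.0):
    """Simple exponential-baseline proportional-hazards data, independent of
    the package's Gompertz simulator (used as a neutral fixture generator)."""
    rng = np.random.default_rng(seed)
    beta = np.asarray(beta, dtype=np.float64)
    p = beta.shape[0]
    X = rng.standard_normal((n, p))
    T = -np.log(rng.uniform(size=n)) / np.exp(X @ beta)
    if censor_scale is None:
        time, status = T, np.ones(n, dtype=int)
    else:
        C = rng.exponential(censor_scale, size=n)
        time = np.minimum(T, C)
        status = (T <= C).astype(int)
    time = np.maximum(time, 1e-12)
    return SurvivalDataset(time, status, X)


@pytest.fixture
def small_data():
    """n=30, p=3, mixed censoring; full rank."""
    return make_exp_cox_data(11, 30, [0.8, -0.5, 0.3])


@pytest.fixture
def midsize_data():
    """n=50, p=3 for MLE-equivalence checks."""
    return make_exp_cox_data(7, 50, [0.8, -0.5, 0.3])
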