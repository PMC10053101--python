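import numpy as np
import pytest

from apkin import synthetic_data as sd


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def noise_free():
    """Factory: noise-free dataset from a named preset."""

    def make(name, **kw):
        spec = sd.preset(name, noise_sd=0.0, **kw)
        if spec.model == "michaelis_menten":
            return sd.gen_kinetic(spec)
        if spec.model == "sigmoid_4pl":
            return sd.gen_dose_response(spec)
        return sd.gen_thermal(spec)

    return make


def ols_oracle(X, y):
    """Closed-form normal-equations OLS with coefficient SEs and t-test
    p-values — the independent linear-regression oracle used across tests."""
    from scipy import stats

    X = np.asarray(X, float)
    y = np.asarray(y, float)
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    resid = y - X @ beta
    dof = len(y) - X.shape[1]
    sigma2 = resid @ resid / dof
    se = np.sqrt(np.diag(sigma2 * np.linalg.inv(X.T @ X)))
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = np.where(se > 0, beta / se, np.where(beta == 0, 0.0, np.inf))
    pvals = 2 * stats.t.sf(np.abs(tvals), dof)
    return beta, se, pvals, dof
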