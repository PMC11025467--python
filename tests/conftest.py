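import numpy as np
import pandas as pd
import pytest

from stemflux import ScenarioConfig, generate_campaign_dataset


@pytest.fixture(scope="session")
def flux_bundle():
    """Default two-season synthetic bundle without dendrometer series."""
    return generate_campaign_dataset(
        ScenarioConfig(seed=42), include_dendrometer=False
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def ols_normal_equations(X, y):
    """Closed-form OLS oracle: coefficients and classical standard errors."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ X.T @ y
    resid = y - X @ beta
    dof = X.shape[0] - X.shape[1]
    sigma2 = resid @ resid / dof
    se = np.sqrt(np.diag(sigma2 * xtx_inv))
    return beta, se


def simple_dendro_frame(diameters, start="2016-06-01", freq="h"):
    ts = pd.date_range(start, periods=len(diameters), freq=freq)
    return pd.DataFrame({"timestamp": ts, "diameter": np.asarray(diameters, float)})
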