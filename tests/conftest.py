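import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import osteorate as ost

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def three_tip_tree():
    """((A:1,B:1):1,C:2); — root age 2."""
    return ost.read_tree("((A:1,B:1):1,C:2);")


@pytest.fixture
def star_tree_factory():
    def make(n, depth=1.0, prefix="t"):
        nwk = "(" + ",".join(f"{prefix}{i}:{depth}" for i in range(n)) + ");"
        return ost.read_tree(nwk)

    return make


@pytest.fixture
def five_tip_tree():
    return ost.read_tree("((A:1,B:1):1,(C:0.5,D:0.5):1.5,E:2);")


@pytest.fixture
def rng():
    return np.random.default_rng(20251001)


def brute_force_gls(y, X, C):
    """Independent PGLS oracle: explicit normal equations and inverses.

    Returns (beta, se, t, p, r2) for design X (intercept NOT included; it is
    prepended here) against covariance C.
    """
    from scipy import stats as st

    y = np.asarray(y, float)
    Xm = np.column_stack([np.ones(len(y)), np.asarray(X, float)])
    Ci = np.linalg.inv(C)
    XtCiX = Xm.T @ Ci @ Xm
    beta = np.linalg.solve(XtCiX, Xm.T @ Ci @ y)
    r = y - Xm @ beta
    n, k = Xm.shape
    rss = r @ Ci @ r
    sigma2 = rss / (n - k)
    se = np.sqrt(np.diag(sigma2 * np.linalg.inv(XtCiX)))
    t = beta / se
    p = 2 * st.t.sf(np.abs(t), n - k)
    ones = np.ones(n)
    mu = (ones @ Ci @ y) / (ones @ Ci @ ones)
    tss = (y - mu) @ Ci @ (y - mu)
    return beta, se, t, p, 1 - rss / tss


@pytest.fixture
def gls_oracle():
    return brute_force_gls
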