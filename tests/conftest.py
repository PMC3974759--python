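import math

import numpy as np
import pytest
from scipy import stats

import omicascade as oc


def ols_oracle(x, y):
    """Textbook simple-OLS slope test, written independently of the package.

    beta = S_xy / S_xx, se from the residual sum of squares with n-2 df,
    p from the two-sided t distribution.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = x.size
    xb, yb = x.mean(), y.mean()
    sxx = float(((x - xb) ** 2).sum())
    syy = float(((y - yb) ** 2).sum())
    sxy = float(((x - xb) * (y - yb)).sum())
    beta = sxy / sxx
    resid = y - (yb + beta * (x - xb))
    s2 = float((resid**2).sum()) / (n - 2)
    se = math.sqrt(s2 / sxx)
    t = beta / se
    p = 2.0 * float(stats.t.sf(abs(t), n - 2))
    r = sxy / math.sqrt(sxx * syy)
    return beta, se, t, p, r


@pytest.fixture
def oracle():
    return ols_oracle


@pytest.fixture(scope="session")
def single_triad_cohort():
    """n=500 cohort with one planted triad: recoverable through all 6 steps."""
    spec = oc.CohortSpec(
        n_samples=500, n_snps=300, n_genes=400, n_mirnas=80,
        n_planted_triads=1, seed=0,
    )
    return oc.generate_cohort(spec)


@pytest.fixture(scope="session")
def small_null_cohort():
    spec = oc.CohortSpec(
        n_samples=58, n_snps=60, n_genes=150, n_mirnas=30, seed=5,
    )
    return oc.generate_null_cohort(spec)
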