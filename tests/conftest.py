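import numpy as np
import pytest

from parenclitic import ExpressionDataset


@pytest.fixture
def rng():
    return np.random.default_rng(20240517)


@pytest.fixture
def small_dataset(rng):
    """Random 6 instances x 4 features dataset."""
    values = rng.normal(size=(6, 4))
    return ExpressionDataset(
        values=values,
        instance_ids=[f"s{i}" for i in range(1, 7)],
        feature_ids=["A", "B", "C", "D"],
    )


def ols_oracle(x, y):
    """Closed-form normal-equation OLS: solve the 2x2 system directly.

    Independent of the package's fitting path; returns (slope, intercept,
    residual_std with ddof=1).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = x.size
    A = np.array([[n, x.sum()], [x.sum(), (x * x).sum()]])
    b = np.array([y.sum(), (x * y).sum()])
    intercept, slope = np.linalg.solve(A, b)
    resid = y - (slope * x + intercept)
    resid_std = np.sqrt(((resid - resid.mean()) ** 2).sum() / (n - 1))
    return slope, intercept, resid_std
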