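import numpy as np
import pandas as pd
import pytest

from nomostack.cohort import CohortTable
from nomostack.simulate import builtin_profile, generate


@pytest.fixture(scope="session")
def builtin_cohort() -> CohortTable:
    """A moderately sized cohort drawn from the builtin group profiles."""
    return generate(builtin_profile(n=400, seed=11))


@pytest.fixture()
def toy_cohort() -> CohortTable:
    """Tiny hand-built cohort with known values for exact assertions."""
    feats = pd.DataFrame(
        {
            "PSA": [2.0, 4.0, 6.0, 1500.0, 999.9],
            "Interleukin-6": [0.8, 2.0, 3.0, 4.0, 5.0],
            "Age": [60.0, 61.0, 62.0, 63.0, 64.0],
        },
        index=[f"p{i}" for i in range(5)],
    )
    risk = pd.Series([1, 1, 2, 3, 3], index=feats.index)
    return CohortTable(feats, risk)


def make_ordinal_sample(
    beta: np.ndarray, theta: np.ndarray, n: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Draw (X, y) from a proportional-odds model with standard-normal covariates."""
    from scipy.special import expit

    beta = np.atleast_1d(beta)
    X = rng.standard_normal((n, len(beta)))
    eta = X @ beta
    cum = expit(theta[None, :] - eta[:, None])
    u = rng.uniform(size=n)
    y = 1 + (u[:, None] > cum).sum(axis=1)
    return X, y
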