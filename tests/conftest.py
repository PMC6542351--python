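import numpy as np
import pandas as pd
import pytest

from kpsize.data import CovariateSpec, MunicipalityTable


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def small_table():
    """Ten municipalities, one binary covariate, six sampled."""
    df = pd.DataFrame(
        {
            "municipality_id": [f"m{i}" for i in range(10)],
            "province_id": ["p1"] * 5 + ["p2"] * 5,
            "denom": [100.0, 200, 150, 300, 250, 120, 180, 220, 90, 310],
            "sampled": [1, 1, 0, 1, 0, 1, 0, 1, 0, 1],
            "count": [5.0, 10, np.nan, 12, np.nan, 3, np.nan, 8, np.nan, 9],
            "z": [1.0, 0, 1, 0, 1, 1, 0, 0, 1, 0],
        }
    )
    return MunicipalityTable(df)


@pytest.fixture
def binary_spec():
    return CovariateSpec(population="test", covariates=("z",))


@pytest.fixture
def null_spec():
    """Intercept-only models: no covariates at all."""
    return CovariateSpec(population="test", covariates=())


def random_table(rng, k=40, rate=0.02, covariate_driven=False):
    """A random small country with a binary covariate.

    With ``covariate_driven`` the covariate shifts both the sampling
    probability and the count rate, giving the weighting something to do.
    """
    z = rng.binomial(1, 0.4, k).astype(float)
    denom = rng.integers(500, 5000, k).astype(float)
    p_s = 0.3 + 0.4 * z if covariate_driven else np.full(k, 0.5)
    sampled = rng.binomial(1, p_s)
    if sampled.sum() == 0:
        sampled[rng.integers(0, k)] = 1
    if sampled.sum() == k:
        sampled[rng.integers(0, k)] = 0
    r = rate * (1 + z) if covariate_driven else np.full(k, rate)
    counts = rng.binomial(denom.astype(int), r).astype(float)
    df = pd.DataFrame(
        {
            "municipality_id": [f"m{i}" for i in range(k)],
            "province_id": "p1",
            "denom": denom,
            "sampled": sampled,
            "count": np.where(sampled == 1, counts, np.nan),
            "z": z,
        }
    )
    if df.loc[df["sampled"] == 1, "count"].sum() == 0:
        df.loc[df["sampled"] == 1, "count"] += 1.0
    return MunicipalityTable(df)
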