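"""Sampling model, weights, positivity and balance diagnostics."""

import numpy as np
import pandas as pd
import pytest

from kpsize import _glm
from kpsize.data import CovariateSpec, MunicipalityTable, ValidationError
from kpsize.sampling import (
    balance_table,
    compute_weights,
    fit_sampling_model,
    positivity_table,
)

from conftest import random_table


def _table_with_sampling(z, sampled):
    k = len(z)
    counts = np.where(np.asarray(sampled) == 1, 1.0, np.nan)
    return MunicipalityTable(
        pd.DataFrame(
            {
                "municipality_id": [f"m{i}" for i in range(k)],
                "province_id": "p",
                "denom": 100.0,
                "sampled": sampled,
                "count": counts,
                "z": np.asarray(z, float),
            }
        )
    )


def test_saturated_2x2_probabilities_and_weights_exact():
    # Z=1: 8/10 sampled; Z=0: 2/10 sampled -> fitted 0.8 / 0.2, weights 1.25 / 5
    z = [1.0] * 10 + [0.0] * 10
    s = [1] * 8 + [0] * 2 + [1] * 2 + [0] * 8
    table = _table_with_sampling(z, s)
    spec = CovariateSpec(population="t", covariates=("z",))
    fit = fit_sampling_model(table, spec)
    assert fit.fitted_prob[:10] == pytest.approx(0.8, abs=1e-9)
    assert fit.fitted_prob[10:] == pytest.approx(0.2, abs=1e-9)
    w = compute_weights(fit, table)
    assert sorted(set(np.round(w, 9))) == [1.25, 5.0]
    assert len(w) == table.n_sampled
    assert np.all(w >= 1.0)
    # saturated weighting exactly recovers the full-population covariate mean
    zs = table.frame.loc[table.sampled_mask, "z"].to_numpy()
    assert float(np.sum(w * zs) / np.sum(w)) == pytest.approx(0.5, abs=1e-9)


def test_null_sampling_model_mean_calibration(rng):
    k = 500
    z = rng.normal(size=k)
    sampled = rng.binomial(1, 0.3, k)
    table = _table_with_sampling(z, sampled)
    spec = CovariateSpec(
        population="t", covariates=("z",), continuous=("z",)
    )
    fit = fit_sampling_model(table, spec)
    # intercept score equation: fitted probabilities sum to the sampled count
    assert fit.fitted_prob.sum() == pytest.approx(table.n_sampled, abs=1e-8)
    assert fit.fitted_prob.mean() == pytest.approx(sampled.mean(), abs=1e-8)
    assert np.all((fit.fitted_prob > 0.1) & (fit.fitted_prob < 0.6))


def test_separation_reported():
    z = [1.0] * 10 + [0.0] * 10
    s = [1] * 10 + [0] * 10
    table = _table_with_sampling(z, s)
    spec = CovariateSpec(population="t", covariates=("z",))
    with pytest.raises(_glm.SeparationError):
        fit_sampling_model(table, spec)


def test_all_sampled_rejected():
    table = _table_with_sampling([0.0, 1.0, 0.5], [1, 1, 1])
    with pytest.raises(ValidationError):
        fit_sampling_model(table, CovariateSpec(population="t", covariates=("z",)))


def test_positivity_counts_and_empty_strata(rng):
    table = random_table(rng, k=154)
    pos = positivity_table(table, binning={"z": [-0.5, 0.5, 1.5]})
    f = pos.frame
    assert f["n"].sum() == 154
    assert f["n_sampled"].sum() == table.n_sampled
    assert ((f["prop_sampled"] >= 0) & (f["prop_sampled"] <= 1)).all()
    # row order of the table must not matter
    shuffled = MunicipalityTable(
        table.frame.sample(frac=1.0, random_state=1).reset_index(drop=True)
    )
    pos2 = positivity_table(shuffled, binning={"z": [-0.5, 0.5, 1.5]})
    pd.testing.assert_frame_equal(pos.frame, pos2.frame)


def test_positivity_single_stratum_and_violation():
    z = np.zeros(154)
    s = np.zeros(154, int)
    s[:30] = 1
    table = _table_with_sampling(z, s)
    pos = positivity_table(table, binning={"z": [-1.0, 1.0]})
    assert pos.frame.loc[0, "prop_sampled"] == pytest.approx(30 / 154)
    assert not pos.violated
    # two strata, one with municipalities but zero sampled
    z2 = np.r_[np.zeros(20), np.ones(10)]
    s2 = np.r_[np.ones(10, int), np.zeros(20, int)]
    t2 = _table_with_sampling(z2, s2)
    pos2 = positivity_table(t2, binning={"z": [-0.5, 0.5, 1.5]})
    assert pos2.violated and len(pos2.empty_strata) == 1


def test_positivity_out_of_range_bin_error(rng):
    table = random_table(rng)
    with pytest.raises(ValidationError):
        positivity_table(table, binning={"z": [0.2, 0.8]})


def test_balance_zero_when_everyone_sampled():
    z = np.linspace(0, 1, 12)
    table = _table_with_sampling(z, np.ones(12, int))
    spec = CovariateSpec(population="t", covariates=("z",))
    bal = balance_table(table, spec)
    assert bal.loc["z", "std_diff"] == pytest.approx(0.0, abs=1e-12)


def test_balance_hand_arithmetic_and_constant_covariate(rng):
    table = random_table(rng, k=60, covariate_driven=True)
    df = table.frame.assign(const=1.0)
    table2 = MunicipalityTable(df)
    spec = CovariateSpec(population="t", covariates=("z", "const"))
    bal = balance_table(table2, spec)
    x = df["z"].to_numpy()
    xs = x[table2.sampled_mask]
    pooled = np.sqrt((np.var(x, ddof=1) + np.var(xs, ddof=1)) / 2)
    assert bal.loc["z", "std_diff"] == pytest.approx(
        (xs.mean() - x.mean()) / pooled, rel=1e-12
    )
    assert pd.isna(bal.loc["const", "std_diff"])


def test_weight_sum_estimates_number_of_municipalities(rng):
    # E[sum of weights] = k when the sampling model is correct
    sums = []
    for _ in range(200):
        table = random_table(rng, k=80, covariate_driven=True)
        spec = CovariateSpec(population="t", covariates=("z",))
        try:
            fit = fit_sampling_model(table, spec)
        except _glm.GlmError:
            continue
        sums.append(fit.weight_sum)
    sums = np.array(sums)
    se = sums.std(ddof=1) / np.sqrt(len(sums))
    assert abs(sums.mean() - 80) < 4 * se + 1e-9
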