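"""The synthetic country generator: determinism, designed confounding,
ignorability by construction, and the packaged fixture."""

import numpy as np
import pandas as pd
import pytest

from kpsize.data import read_municipality_table
from kpsize.synthetic import (
    Scenario,
    default_scenario,
    dr_like_fixture,
    generate_country,
)


def test_same_seed_identical_different_seed_differs():
    a = generate_country(default_scenario(), seed=9)
    b = generate_country(default_scenario(), seed=9)
    c = generate_country(default_scenario(), seed=10)
    pd.testing.assert_frame_equal(a.frame, b.frame)
    assert not a.frame["count"].equals(c.frame["count"])


def test_homogeneous_country_constant_rate():
    sc = default_scenario(
        beta={"intercept": float(np.log(0.037))}, rate_dispersion_sd=0.0
    )
    country = generate_country(sc, seed=2)
    assert country.frame["true_pi"].to_numpy() == pytest.approx(0.037, abs=1e-12)
    # national proportion is 0.037 up to Poisson noise, regardless of sampling
    assert country.pi_true == pytest.approx(0.037, rel=0.05)


def test_fixture_dimensions_and_truth_range():
    for seed in (1, 2, 7):
        t = dr_like_fixture(seed)
        assert t.n_total == 154
        assert t.n_sampled == 50
        assert t.frame["province_id"].nunique() == 31
        assert (t.frame["sampling_stage"] == "purposive").sum() == 30
        assert (t.frame["sampling_stage"] == "random").sum() == 20
        assert 0.02 < t.pi_true < 0.06


def test_fixture_three_populations_share_design(tmp_path):
    f = dr_like_fixture(5, population="fsw")
    m = dr_like_fixture(5, population="msm")
    g = dr_like_fixture(5, population="tgw")
    shared = ["log_density", "poverty", "denom", "sampled"]
    pd.testing.assert_frame_equal(f.frame[shared], m.frame[shared])
    # intercept ordering carries through to the national proportions
    assert f.pi_true > m.pi_true > g.pi_true
    assert 0.006 < m.pi_true < 0.02
    assert 0.0008 < g.pi_true < 0.004
    # and the observed table round-trips through the CSV layer
    path = tmp_path / "fix.csv"
    f.to_observed().to_csv(path)
    back = read_municipality_table(path)
    assert back.equals(f.to_observed())


def test_counts_never_exceed_denominator():
    for model in ("poisson", "binomial"):
        t = generate_country(default_scenario(count_model=model), seed=3)
        assert (t.frame["true_count"] <= t.frame["denom"]).all()
        assert (t.frame["true_count"] >= 0).all()


def test_purposive_selection_biases_sampled_rates():
    """The default purposive stage prefers dense, less-poor, touristy areas
    where the key population *proportion* is lower, so the sampled mean rate
    sits below the national mean — the mechanism that biases the crude
    estimator downward."""
    diffs = []
    for seed in range(60):
        t = generate_country(default_scenario(), seed=seed)
        df = t.frame
        s = df["sampling_stage"] == "purposive"
        diffs.append(df.loc[s, "true_pi"].mean() - df["true_pi"].mean())
    assert np.mean(diffs) < -0.002  # bounded away from zero


def test_positive_density_effect_flips_sampled_rate_direction():
    # with a positive density effect, perceived-risk selection on density
    # picks municipalities with *higher* rates
    beta = {"intercept": -4.0, "log_density": 0.3}
    sc = default_scenario(beta=beta)
    diffs = []
    for seed in range(60):
        t = generate_country(sc, seed=seed)
        df = t.frame
        s = df["sampling_stage"] == "purposive"
        diffs.append(df.loc[s, "true_pi"].mean() - df["true_pi"].mean())
    assert np.mean(diffs) > 0.0


def test_selection_ignorable_given_covariates():
    """Selection depends on covariates plus independent noise only: the
    municipality-level rate residual (beyond the covariates) has the same
    mean among sampled and unsampled rows."""
    sc = default_scenario(rate_dispersion_sd=0.4)
    resid_s, resid_u = [], []
    for seed in range(80):
        t = generate_country(sc, seed=seed)
        df = t.frame
        lin = np.full(len(df), sc.beta["intercept"])
        for name, c in sc.beta.items():
            if name != "intercept":
                lin += c * df[name].to_numpy()
        resid = np.log(df["true_pi"].to_numpy()) - lin
        m = df["sampled"] == 1
        resid_s.append(resid[m].mean())
        resid_u.append(resid[~m].mean())
    gap = np.mean(resid_s) - np.mean(resid_u)
    se = np.std(np.array(resid_s) - np.array(resid_u), ddof=1) / np.sqrt(80)
    assert abs(gap) < 4 * se + 0.01


def test_generator_mean_matches_rate():
    sc = default_scenario(beta={"intercept": float(np.log(0.01))})
    ratios = [generate_country(sc, seed=s).pi_true for s in range(40)]
    assert np.mean(ratios) == pytest.approx(0.01, rel=0.02)


def test_infeasible_scenario_rejected():
    sc = default_scenario(beta={"intercept": float(np.log(0.45)), "poverty": 2.0})
    with pytest.raises(ValueError, match="extreme"):
        generate_country(sc, seed=1)


def test_scenario_validation():
    with pytest.raises(ValueError):
        Scenario(k=40, n_purposive=30, n_random=20)
    with pytest.raises(ValueError):
        Scenario(selection="cluster")
    with pytest.raises(ValueError):
        Scenario(count_model="negbin")


def test_logistic_selection_mode_targets_expected_sample_size():
    sc = default_scenario(selection="logistic")
    n_purp = [
        (generate_country(sc, seed=s).frame["sampling_stage"] == "purposive").sum()
        for s in range(40)
    ]
    assert abs(np.mean(n_purp) - 30) < 3.0
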