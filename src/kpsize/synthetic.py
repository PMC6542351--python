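"""Synthetic countries with known truth for testing and simulation.

The generator emulates a Dominican-Republic-like setting: 154 municipalities
nested in 31 provinces, a candidate population per municipality, contextual
covariates (log population density, poverty, tourism, HIV prevalence,
adolescent pregnancy, female education, border/port, university), true key
population counts driven by the covariates, and a two-stage sample — a
purposive stage that preferentially picks municipalities scoring high on a
perceived-risk index of the same covariates, then a random stage drawn
uniformly from the remainder.  Direct-estimate counts are revealed only for
sampled municipalities; the hidden truth travels along for evaluation.

Selection depends on the covariates plus independent noise only, never on
the counts themselves, so conditional exchangeability given the covariates
holds by construction while marginal exchangeability fails — exactly the
structure the estimators are built for.

Two purposive-stage mechanisms are provided.  ``top_n`` ranks a
Gumbel-perturbed risk index and takes the highest-scoring municipalities
(noisy stakeholder prioritization; the logistic sampling model is then only
approximately correct — a realistic stress test).  ``logistic`` draws
independent Bernoulli selections with logit probabilities calibrated to the
same expected sample size, making the fitted sampling model genuinely
correctly specified — the mode the simulation study uses for its
"both models correct" cell.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .data import TruthTable
from .surfaces import ClusterPoints

__all__ = [
    "Scenario",
    "generate_country",
    "dr_like_fixture",
    "generate_cluster_fixture",
    "default_scenario",
]

#: per-population default log-rate coefficients; intercepts calibrated once so
#: the implied national proportions sit near 3.7% (FSW-like), 1.2% (MSM-like)
#: and 0.19% (TGW-like)
_BETA_EFFECTS = {
    "log_density": -0.25,
    "poverty": 2.2,
    "tourism": 0.35,
    "hiv_prev": 6.0,
}
_BETA_INTERCEPTS = {"fsw": -3.00, "msm": -4.13, "tgw": -5.97}

#: purposive-stage risk index: loads positively on density and tourism and
#: negatively on poverty (urban, touristy, less-poor areas are perceived as
#: priority), inducing the designed confounding with the outcome model above
_ALPHA_DEFAULT = {
    "log_density": 1.0,
    "poverty": -4.0,
    "tourism": 0.8,
}

#: covariate-generator tunables (location/scale/concentration parameters)
_COV_PARAMS = {
    "log_density_mean": 4.5,
    "log_density_sd": 1.2,
    "poverty_logit_intercept": -0.5,
    "poverty_logit_density": -0.55,
    "poverty_concentration": 10.0,
    "hiv_base": 0.015,
    "hiv_poverty": 0.02,
    "hiv_concentration": 300.0,
    "denom_log_mean": 9.2,
    "denom_log_density": 0.95,
    "denom_log_sd": 0.35,
}


@dataclass(frozen=True)
class Scenario:
    """Everything needed to generate one synthetic country."""

    k: int = 154
    n_provinces: int = 31
    n_purposive: int = 30
    n_random: int = 20
    population: str = "fsw"
    beta: Mapping[str, float] = field(default_factory=dict)
    alpha: Mapping[str, float] = field(default_factory=lambda: dict(_ALPHA_DEFAULT))
    selection: str = "top_n"  # or "logistic"
    count_model: str = "poisson"  # or "binomial"
    #: SD of an optional lognormal municipality-level rate deviation around
    #: the covariate-driven mean (residual heterogeneity beyond the
    #: covariates), centered so E[multiplier] = 1.  The default surface is
    #: exactly log-linear in the covariates (no extra dispersion); positive
    #: values are a robustness stress switch for the estimators' working
    #: models.
    rate_dispersion_sd: float = 0.0
    gumbel_scale: float = 1.0
    pi_cap: float = 0.5
    max_cap_frac: float = 0.05
    covariate_params: Mapping[str, float] = field(
        default_factory=lambda: dict(_COV_PARAMS)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_purposive + self.n_random > self.k:
            raise ValueError("cannot sample more municipalities than exist")
        if self.selection not in ("top_n", "logistic"):
            raise ValueError(f"unknown selection mode {self.selection!r}")
        if self.count_model not in ("poisson", "binomial"):
            raise ValueError(f"unknown count model {self.count_model!r}")
        if not self.beta:
            beta = dict(_BETA_EFFECTS)
            beta["intercept"] = _BETA_INTERCEPTS.get(self.population, -3.0)
            object.__setattr__(self, "beta", beta)

    def replace(self, **kw) -> "Scenario":
        return dataclasses.replace(self, **kw)


def default_scenario(population: str = "fsw", **overrides) -> Scenario:
    """The packaged DR-like scenario for the given key population."""
    return Scenario(population=population, **overrides)


def _draw_covariates(k: int, params: Mapping[str, float], rng: np.random.Generator):
    p = dict(_COV_PARAMS)
    p.update(params)
    z = rng.standard_normal(k)
    log_density = p["log_density_mean"] + p["log_density_sd"] * z
    pov_mean = expit(p["poverty_logit_intercept"] + p["poverty_logit_density"] * z)
    phi = p["poverty_concentration"]
    poverty = rng.beta(pov_mean * phi, (1 - pov_mean) * phi)
    hiv_mean = p["hiv_base"] + p["hiv_poverty"] * poverty
    phi_h = p["hiv_concentration"]
    hiv_prev = rng.beta(hiv_mean * phi_h, (1 - hiv_mean) * phi_h)
    tourism = rng.binomial(1, expit(-1.6 + 0.9 * z)).astype(float)
    border_port = rng.binomial(1, expit(-1.9 + 0.4 * z)).astype(float)
    university = rng.binomial(1, expit(-1.8 + 1.4 * z)).astype(float)
    adol_mean = 0.06 + 0.08 * poverty
    adolescent_pregnancy = rng.beta(adol_mean * 150.0, (1 - adol_mean) * 150.0)
    education_years = rng.normal(10.5 - 3.0 * poverty, 0.8)
    denom = np.round(
        np.exp(
            p["denom_log_mean"]
            + p["denom_log_density"] * z
            + p["denom_log_sd"] * rng.standard_normal(k)
        )
    )
    denom = np.maximum(denom, 300.0)
    return pd.DataFrame(
        {
            "log_density": log_density,
            "poverty": poverty,
            "tourism": tourism,
            "hiv_prev": hiv_prev,
            "adolescent_pregnancy": adolescent_pregnancy,
            "education_years": education_years,
            "border_port": border_port,
            "university": university,
        }
    ), denom


def _linear_index(cov: pd.DataFrame, coefs: Mapping[str, float]) -> np.ndarray:
    out = np.full(len(cov), float(coefs.get("intercept", 0.0)))
    for name, c in coefs.items():
        if name == "intercept":
            continue
        out += c * cov[name].to_numpy()
    return out


def _select_municipalities(
    scenario: Scenario, cov: pd.DataFrame, rng: np.random.Generator
) -> np.ndarray:
    """Return sampling_stage labels: 'purposive', 'random', 'none'."""
    k = scenario.k
    index = _linear_index(cov, scenario.alpha)
    stage = np.array(["none"] * k, dtype=object)
    if scenario.selection == "top_n":
        noisy = index + rng.gumbel(0.0, scenario.gumbel_scale, k)
        purposive = np.argsort(-noisy)[: scenario.n_purposive]
    else:
        # Bernoulli with the same risk index, intercept calibrated so the
        # expected purposive sample size matches n_purposive
        def excess(c0):
            return expit(c0 + index).sum() - scenario.n_purposive

        c0 = brentq(excess, -40.0, 40.0)
        sel = rng.random(k) < expit(c0 + index)
        purposive = np.where(sel)[0]
    stage[purposive] = "purposive"
    remainder = np.where(stage == "none")[0]
    n_rand = min(scenario.n_random, len(remainder))
    random_pick = rng.choice(remainder, size=n_rand, replace=False)
    stage[random_pick] = "random"
    return stage


def generate_country(
    scenario: Scenario, seed: int | None = None
) -> TruthTable:
    """Generate one synthetic country under the scenario.

    Streams for covariates, selection and counts are spawned independently
    from the seed, so two scenarios differing only in the outcome intercept
    share covariates and sampling for the same seed.  Raises ``ValueError``
    when the rate cap (0.5 by default) binds for more than 5% of
    municipalities — the scenario is then too extreme to be meaningful.
    """
    seed = scenario.seed if seed is None else seed
    if isinstance(seed, np.random.SeedSequence):
        ss = seed
    else:
        ss = np.random.SeedSequence(seed)
    rng_cov, rng_sel, rng_count = (np.random.default_rng(c) for c in ss.spawn(3))

    cov, denom = _draw_covariates(scenario.k, scenario.covariate_params, rng_cov)
    log_pi = _linear_index(cov, scenario.beta)
    if scenario.rate_dispersion_sd > 0:
        sd = scenario.rate_dispersion_sd
        log_pi = log_pi + rng_count.normal(-0.5 * sd * sd, sd, scenario.k)
    pi = np.exp(log_pi)
    capped = pi > scenario.pi_cap
    if capped.mean() > scenario.max_cap_frac:
        raise ValueError(
            f"scenario too extreme: true rate capped for {capped.mean():.1%} "
            "of municipalities"
        )
    pi = np.minimum(pi, scenario.pi_cap)

    stage = _select_municipalities(scenario, cov, rng_sel)
    sampled = (stage != "none").astype(int)

    if scenario.count_model == "poisson":
        y = rng_count.poisson(denom * pi).astype(float)
        y = np.minimum(y, denom)
    else:
        y = rng_count.binomial(denom.astype(int), pi).astype(float)

    k = scenario.k
    prov_cycle = np.repeat(
        np.arange(scenario.n_provinces), int(np.ceil(k / scenario.n_provinces))
    )[:k]
    rng_cov.shuffle(prov_cycle)

    df = pd.DataFrame(
        {
            "municipality_id": [f"M{i + 1:03d}" for i in range(k)],
            "province_id": [f"P{p + 1:02d}" for p in prov_cycle],
            "denom": denom,
            "sampled": sampled,
            "count": np.where(sampled == 1, y, np.nan),
        }
    )
    df = pd.concat([df, cov], axis=1)
    df["true_count"] = y
    df["true_pi"] = pi
    df["sampling_stage"] = stage
    return TruthTable(df)


def dr_like_fixture(seed: int, population: str = "fsw") -> TruthTable:
    """The packaged default country: 154 municipalities in 31 provinces,
    30 purposive + 20 random sampled, national rate near 3.7% (fsw),
    1.2% (msm) or 0.19% (tgw).

    Calling with the same seed and different populations shares covariates
    and the sampled set (only the counts change), mirroring three key
    populations observed through one study design.
    """
    return generate_country(default_scenario(population), seed=seed)


def generate_cluster_fixture(
    surface_coefficients,
    n_points: int,
    seed: int,
    noise_sd: float = 0.0,
    extent: tuple[float, float, float, float] = (0.0, 10.0, 0.0, 10.0),
) -> ClusterPoints:
    """Cluster points on a rectangle with a linear indicator surface.

    ``surface_coefficients`` is (a, b, c) for value = a + b*x + c*y; optional
    Gaussian noise on top.  With zero noise, linear interpolation must
    reproduce the surface exactly inside the hull — the oracle used by the
    surface tests.
    """
    if n_points < 3:
        raise ValueError("need at least 3 cluster points")
    a, b, c = surface_coefficients
    rng = np.random.default_rng(seed)
    x0, x1, y0, y1 = extent
    x = rng.uniform(x0, x1, n_points)
    y = rng.uniform(y0, y1, n_points)
    value = a + b * x + c * y + (
        rng.normal(0.0, noise_sd, n_points) if noise_sd > 0 else 0.0
    )
    return ClusterPoints(x=x, y=y, value=value)
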