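"""The four national size estimators and their variance estimators.

The estimand is the national proportion pi = sum_i Y_i / sum_i N_i, where
Y_i is the key population count and N_i the candidate population in
municipality i, with Y_i observed only in sampled municipalities (S_i = 1).

complete_case
    Intercept-only Poisson regression of Y on an offset log N over sampled
    rows.  The MLE is exactly the ratio sum_s Y / sum_s N; consistent only
    under unconditional exchangeability of sampled and unsampled areas.
ipsw
    The same model weighted by W_i = 1 / Pr(S_i=1 | Z_i) from the logistic
    sampling model, giving the Hajek-type ratio sum_s W Y / sum_s W N.
    Consistent when the sampling model is correct.  CI from the weighted
    robust sandwich variance of the log rate.
mi
    Multiple imputation: a Poisson outcome model for Y given spline-expanded
    Z on sampled rows; for each of M imputations, coefficients are drawn from
    MVN(beta_hat, Sigma_hat) and unsampled counts from Poisson(N_i *
    exp(Z_i beta^(m))); an intercept-only analysis model over all rows gives
    log pi^(m); Rubin's rules pool on the log scale.  Consistent when the
    outcome model is correct.
aipw
    The "regression" augmented-IPSW estimator: predictions from the
    IPSW-weighted outcome model for every municipality, then
    pi_hat = sum_all Y_hat / sum_all N.  Doubly robust — consistent when
    either working model is correct — with a nonparametric bootstrap
    (municipalities resampled with replacement) for the CI.

All intervals are built on the log scale and exponentiated, so they stay
positive and are comparable across methods.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import _glm
from .data import CovariateSpec, MunicipalityTable, SizeEstimate, ValidationError
from .splines import build_design
from .sampling import fit_sampling_model, SamplingFit

__all__ = [
    "OutcomeModelFit",
    "ImputationDraw",
    "RubinSummary",
    "estimate_complete_case",
    "estimate_ipsw",
    "fit_outcome_model",
    "draw_imputations",
    "estimate_mi",
    "estimate_aipw",
    "national_count",
    "pool_rubin",
]

Z95 = float(stats.norm.ppf(0.975))


# ---------------------------------------------------------------------------
# intercept-only weighted Poisson: closed-form pieces shared by the methods
# ---------------------------------------------------------------------------

def _weighted_rate_fit(y, n, w=None):
    """Fit the intercept-only Poisson with offset log(n) by Newton iteration
    and return (log_pi, robust log-scale variance).

    The MLE equals log(sum w y / sum w n); the fit is still run through the
    Newton solver so the GLM and ratio routes stay independent checks of one
    another.  The sandwich variance for the single coefficient reduces to
    sum[(w(y - n*pi))^2] / (sum w n pi)^2.
    """
    y = np.asarray(y, float)
    n = np.asarray(n, float)
    w = np.ones_like(y) if w is None else np.asarray(w, float)
    if y.sum() <= 0:
        raise ValidationError(
            "all observed counts are zero; the log-rate is unbounded below"
        )
    X = np.ones((len(y), 1))
    fit = _glm.fit_poisson(X, y, np.log(n), weights=w, names=["intercept"])
    log_pi = float(fit.params[0])
    var = float(fit.cov_robust[0, 0])
    return log_pi, var


def _wald_estimate(method, log_pi, log_var, table, meta) -> SizeEstimate:
    se = math.sqrt(max(log_var, 0.0))
    pi = math.exp(log_pi)
    lo, hi = math.exp(log_pi - Z95 * se), math.exp(log_pi + Z95 * se)
    return SizeEstimate(
        method=method,
        pi_hat=pi,
        log_se=se,
        ci_low=lo,
        ci_high=hi,
        national_count=pi * table.denom_total,
        n_total=table.n_total,
        n_sampled=table.n_sampled,
        meta=meta,
    )


def estimate_complete_case(table: MunicipalityTable) -> SizeEstimate:
    """National proportion from the sampled municipalities alone."""
    df = table.frame
    mask = table.sampled_mask
    if mask.sum() == 0:
        raise ValidationError("no sampled municipalities")
    y = df.loc[mask, "count"].to_numpy()
    n = df.loc[mask, "denom"].to_numpy()
    log_pi, var = _weighted_rate_fit(y, n)
    return _wald_estimate("complete_case", log_pi, var, table, {"ci": "sandwich"})


def estimate_ipsw(
    table: MunicipalityTable,
    spec: CovariateSpec,
    sampling_fit: SamplingFit | None = None,
) -> SizeEstimate:
    """Inverse-probability-of-sampling-weighted national proportion."""
    df = table.frame
    mask = table.sampled_mask
    if sampling_fit is None:
        if mask.all():
            # fully sampled country: selection probability is 1 everywhere
            sampling_fit = SamplingFit(
                coefficients=np.array([]),
                design_columns=[],
                fitted_prob=np.ones(len(df)),
                weights=np.ones(int(mask.sum())),
                converged=True,
            )
        else:
            sampling_fit = fit_sampling_model(table, spec)
    y = df.loc[mask, "count"].to_numpy()
    n = df.loc[mask, "denom"].to_numpy()
    w = sampling_fit.weights
    log_pi, var = _weighted_rate_fit(y, n, w)
    ci_label = "weighted sandwich (weights known)"
    if sampling_fit.design is not None and len(sampling_fit.coefficients):
        # joint M-estimation sandwich: the sampling-model coefficients are
        # estimated, and propagating their score equations shrinks the
        # variance of the weighted rate (the known-weights sandwich is
        # conservative)
        var = _ipsw_estimated_weight_var(
            y, n, w, log_pi, sampling_fit, mask
        )
        ci_label = "joint sandwich (weights estimated)"
    meta = {
        "ci": ci_label,
        "weight_sum": sampling_fit.weight_sum,
        "weight_max": float(w.max()),
        "sampling_coefficients": sampling_fit.coefficients,
    }
    return _wald_estimate("ipsw", log_pi, var, table, meta)


def _ipsw_estimated_weight_var(y, n, w, log_pi, sampling_fit, mask) -> float:
    """Variance of log pi_hat treating the IPSW weights as estimated.

    Stacks the logistic score equations with the weighted intercept-only
    Poisson estimating equation and reads off the influence function:
    with A = sum_s w mu, psi_i = S_i w_i (y_i - mu_i),
    C = d(sum psi)/d(alpha) = -sum_s ((1-p_i)/p_i) (y_i - mu_i) x_i', and
    h_i = I_alpha^{-1} x_i (S_i - p_i), the influence of municipality i is
    (psi_i + C h_i)/A and the variance is the sum of its squares.
    """
    X = sampling_fit.design
    p = sampling_fit.fitted_prob
    s = mask.astype(float)
    mu = n * math.exp(log_pi)
    resid = y - mu
    A = float(np.sum(w * mu))
    psi = np.zeros(len(X))
    psi[mask] = w * resid
    C = -((1.0 - p[mask]) / p[mask] * resid) @ X[mask]
    info = (X * (p * (1.0 - p))[:, None]).T @ X
    h = np.linalg.solve(info, (X * (s - p)[:, None]).T).T
    infl = (psi + h @ C) / A
    return float(np.sum(infl**2))


# ---------------------------------------------------------------------------
# outcome model
# ---------------------------------------------------------------------------

@dataclass
class OutcomeModelFit:
    """A Poisson outcome model for counts given covariates.

    Fit on the sampled rows (optionally IPSW-weighted), but the design and
    the predictions ``mu_all`` cover every municipality — spline knots are
    placed on the full country so the basis extends off the sampled subset.
    """

    coefficients: np.ndarray
    covariance: np.ndarray
    design_columns: list[str]
    design_all: np.ndarray
    mu_all: np.ndarray
    weighted: bool

    @property
    def predicted_counts(self) -> np.ndarray:
        return self.mu_all


def fit_outcome_model(
    table: MunicipalityTable,
    spec: CovariateSpec,
    weights: np.ndarray | None = None,
) -> OutcomeModelFit:
    """Poisson regression of Y on spline-expanded Z with offset log N.

    ``weights``, when given, are per-sampled-row IPSW weights (the AIPW
    path); without them the fit is the unweighted imputation model (the MI
    path), whose model-based covariance feeds the posterior coefficient
    draws.
    """
    df = table.frame
    mask = table.sampled_mask
    X_all, names = build_design(df, spec)
    if mask.sum() < X_all.shape[1] + 1:
        raise ValidationError(
            f"only {int(mask.sum())} sampled municipalities for "
            f"{X_all.shape[1]} design columns; reduce the covariate spec"
        )
    y = df.loc[mask, "count"].to_numpy()
    offset = np.log(df.loc[mask, "denom"].to_numpy())
    fit = _glm.fit_poisson(X_all[mask], y, offset, weights=weights, names=names)
    cov = fit.cov_robust if weights is not None else fit.cov_model
    eta_all = np.clip(X_all @ fit.params, -_glm._MAX_ETA, _glm._MAX_ETA)
    mu_all = df["denom"].to_numpy() * np.exp(eta_all)
    return OutcomeModelFit(
        coefficients=fit.params,
        covariance=cov,
        design_columns=names,
        design_all=X_all,
        mu_all=mu_all,
        weighted=weights is not None,
    )


# ---------------------------------------------------------------------------
# multiple imputation
# ---------------------------------------------------------------------------

@dataclass
class ImputationDraw:
    m: int
    beta: np.ndarray
    completed_counts: np.ndarray  # full-length; observed rows untouched


def _psd_root(cov: np.ndarray) -> np.ndarray:
    """Cholesky-like factor, repairing tiny negative eigenvalues by clipping."""
    try:
        return np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        vals, vecs = np.linalg.eigh(cov)
        vals = np.clip(vals, 0.0, None)
        return vecs * np.sqrt(vals)


def draw_imputations(
    fit: OutcomeModelFit,
    table: MunicipalityTable,
    M: int,
    rng: np.random.Generator | int,
) -> list[ImputationDraw]:
    """M proper-MI draws of the unobserved counts.

    Coefficients are drawn from MVN(beta_hat, Sigma_hat); unsampled counts
    from Poisson(N_i exp(Z_i beta^(m))) — a random draw, not the expected
    count, so that between-imputation variance reflects both coefficient and
    count uncertainty and Rubin's rules remain valid.
    """
    if M < 2:
        raise ValidationError("multiple imputation needs M >= 2")
    rng = np.random.default_rng(rng)
    df = table.frame
    mask = table.sampled_mask
    y_obs = df["count"].to_numpy(dtype=float)
    denom = df["denom"].to_numpy()
    root = _psd_root(fit.covariance)
    p = len(fit.coefficients)
    draws = []
    for m in range(1, M + 1):
        beta = fit.coefficients + root @ rng.standard_normal(p)
        eta = np.clip(fit.design_all @ beta, -_glm._MAX_ETA, _glm._MAX_ETA)
        mu = denom * np.exp(eta)
        completed = y_obs.copy()
        imput = rng.poisson(np.minimum(mu[~mask], 1e12)).astype(float)
        completed[~mask] = imput
        draws.append(ImputationDraw(m=m, beta=beta, completed_counts=completed))
    return draws


@dataclass
class RubinSummary:
    """Rubin's-rules pooling of M log-scale estimates."""

    point: float
    within: float
    between: float
    total: float
    df: float
    M: int


def pool_rubin(log_estimates: np.ndarray, within_vars: np.ndarray) -> RubinSummary:
    """Pool per-imputation log estimates and variances.

    point = mean(log pi^(m)); W = mean within-imputation variance;
    B = sample variance of the log estimates; T = W + (1 + 1/M) B.
    Degrees of freedom (M-1)(1 + W/((1+1/M)B))^2, infinite when B = 0.
    """
    logs = np.asarray(log_estimates, float)
    wvars = np.asarray(within_vars, float)
    M = len(logs)
    if M < 2 or len(wvars) != M:
        raise ValidationError("Rubin pooling needs M >= 2 matched estimates/variances")
    point = float(logs.mean())
    within = float(wvars.mean())
    between = float(logs.var(ddof=1))
    total = within + (1.0 + 1.0 / M) * between
    if between > 0:
        df = (M - 1) * (1.0 + within / ((1.0 + 1.0 / M) * between)) ** 2
    else:
        df = math.inf
    return RubinSummary(point=point, within=within, between=between,
                        total=total, df=df, M=M)


def estimate_mi(
    table: MunicipalityTable,
    spec: CovariateSpec,
    M: int = 50,
    seed: int | np.random.Generator | None = None,
) -> SizeEstimate:
    """Multiple-imputation national proportion with Rubin's-rules variance."""
    fit = fit_outcome_model(table, spec)
    draws = draw_imputations(fit, table, M, np.random.default_rng(seed))
    denom = table.frame["denom"].to_numpy()
    logs = np.empty(M)
    wvars = np.empty(M)
    for j, d in enumerate(draws):
        logs[j], wvars[j] = _weighted_rate_fit(d.completed_counts, denom)
    pooled = pool_rubin(logs, wvars)
    se = math.sqrt(pooled.total)
    q = Z95 if not math.isfinite(pooled.df) else float(stats.t.ppf(0.975, pooled.df))
    pi = math.exp(pooled.point)
    meta = {
        "M": M,
        "within": pooled.within,
        "between": pooled.between,
        "rubin_df": pooled.df,
        "outcome_coefficients": fit.coefficients,
        "ci": "Rubin t",
    }
    return SizeEstimate(
        method="mi",
        pi_hat=pi,
        log_se=se,
        ci_low=math.exp(pooled.point - q * se),
        ci_high=math.exp(pooled.point + q * se),
        national_count=pi * table.denom_total,
        n_total=table.n_total,
        n_sampled=table.n_sampled,
        meta=meta,
    )


# ---------------------------------------------------------------------------
# augmented IPSW
# ---------------------------------------------------------------------------

def _table_arrays(df: pd.DataFrame, covariates) -> dict[str, np.ndarray]:
    """Pull the columns the AIPW pipeline needs into plain float arrays."""
    cols = {c: df[c].to_numpy(dtype=float) for c in covariates}
    cols["__denom"] = df["denom"].to_numpy(dtype=float)
    cols["__sampled"] = df["sampled"].to_numpy(dtype=float)
    cols["__count"] = df["count"].to_numpy(dtype=float)
    return cols


def _aipw_log_pi(
    cols: dict[str, np.ndarray],
    sampling_spec: CovariateSpec,
    outcome_spec: CovariateSpec,
    starts: tuple | None = None,
) -> tuple[float, tuple]:
    """log pi_hat of the regression-AIPW estimator on raw column arrays.

    The two working models may use different covariate specs (the
    double-robustness grid breaks one at a time).  Returns the estimate and
    the fitted coefficient pair, reused as warm starts by the bootstrap.
    """
    s = cols["__sampled"]
    mask = s == 1
    s_start, o_start = starts if starts is not None else (None, None)
    if mask.all():
        # fully sampled: selection probability 1, weights 1, and the fitted
        # intercept makes predictions sum to observed counts, so the
        # estimator reduces to the crude ratio
        logit_params = np.array([])
        w = np.ones(int(mask.sum()))
    else:
        if s.min() == s.max():
            raise ValidationError("no sampled municipalities in this table")
        Xs, ns = build_design(cols, sampling_spec)
        logit = _glm.fit_logistic(Xs, s, names=ns, start=s_start)
        logit_params = logit.params
        w = 1.0 / logit.fitted[mask]
    if sampling_spec is outcome_spec and not mask.all():
        Xo, no = Xs, ns
    else:
        Xo, no = build_design(cols, outcome_spec)
    y = cols["__count"][mask]
    denom = cols["__denom"]
    offset = np.log(denom[mask])
    pois = _glm.fit_poisson(
        Xo[mask], y, offset, weights=w, names=no, start=o_start
    )
    eta_all = np.clip(Xo @ pois.params, -_glm._MAX_ETA, _glm._MAX_ETA)
    mu_all = denom * np.exp(eta_all)
    log_pi = float(np.log(mu_all.sum() / denom.sum()))
    return log_pi, (logit_params if len(logit_params) else None, pois.params)


def estimate_aipw(
    table: MunicipalityTable,
    spec: CovariateSpec,
    B: int = 1000,
    seed: int | np.random.Generator | None = None,
    max_discard_frac: float = 0.10,
    outcome_spec: CovariateSpec | None = None,
) -> SizeEstimate:
    """Augmented-IPSW national proportion with a bootstrap CI.

    Point estimate: predictions for all municipalities from the
    IPSW-weighted Poisson outcome model, summed and divided by the national
    denominator.  SE: standard deviation of the log estimate over B
    bootstrap resamples of the municipalities (with replacement, sampling
    indicator carried along).  Replicates where a working model fails
    (separation, lost sampling class, rank deficiency) are discarded and
    counted; more than ``max_discard_frac`` discarded is an error.

    ``outcome_spec`` lets the outcome model use a different covariate spec
    from the sampling model (used by the misspecification experiments);
    by default both use ``spec``.
    """
    if B < 2:
        raise ValidationError("bootstrap needs B >= 2 replicates")
    if outcome_spec is None:
        outcome_spec = spec
    df = table.frame
    covariates = sorted(set(spec.covariates) | set(outcome_spec.covariates))
    cols = _table_arrays(df, covariates)
    log_pi, starts = _aipw_log_pi(cols, spec, outcome_spec)
    rng = np.random.default_rng(seed)
    k = len(df)
    boot = np.empty(B)
    discarded = 0
    got = 0
    attempts = 0
    max_attempts = int(math.ceil(B / (1.0 - max_discard_frac))) + 1
    while got < B and attempts < max_attempts:
        attempts += 1
        idx = rng.integers(0, k, k)
        rcols = {name: arr[idx] for name, arr in cols.items()}
        try:
            val, _ = _aipw_log_pi(rcols, spec, outcome_spec, starts=starts)
        except (_glm.GlmError, ValidationError, np.linalg.LinAlgError):
            discarded += 1
            continue
        # a resample must yield a valid proportion; quasi-separation in the
        # resampled sampling model produces astronomical weights and pushes
        # the plug-in estimate outside (0, 1) — treated as a failed
        # replicate, like outright separation
        if not (math.log(1e-8) < val < 0.0):
            discarded += 1
            continue
        boot[got] = val
        got += 1
    if got < B:
        raise RuntimeError(
            f"bootstrap failed: {discarded} of {attempts} replicates discarded "
            f"(> {max_discard_frac:.0%})"
        )
    se = float(np.std(boot[:B], ddof=1))
    pi = math.exp(log_pi)
    meta = {
        "B": B,
        "discarded_replicates": discarded,
        "ci": "bootstrap SD, log scale",
    }
    return SizeEstimate(
        method="aipw",
        pi_hat=pi,
        log_se=se,
        ci_low=math.exp(log_pi - Z95 * se),
        ci_high=math.exp(log_pi + Z95 * se),
        national_count=pi * table.denom_total,
        n_total=table.n_total,
        n_sampled=table.n_sampled,
        meta=meta,
    )


def national_count(estimate: SizeEstimate, table: MunicipalityTable) -> float:
    """The implied national key population count, pi_hat times total denom."""
    return estimate.pi_hat * table.denom_total
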