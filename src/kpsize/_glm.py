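"""Compact Newton/IRLS solvers for the two GLMs the estimators need.

Only two families ever occur in this package: binomial-logit (the sampling
model, fit to all k municipalities) and Poisson-log with an offset (the
outcome and analysis models, fit to the sampled subset).  Both designs are
tiny — at most a few hundred rows and a dozen-odd columns — but the
simulation study and the AIPW bootstrap refit them hundreds of thousands of
times, so the solvers are written directly on numpy with no per-fit object
construction.  Their coefficients and sandwich variances are cross-checked
against a reference GLM implementation in the test suite.

Conventions: full-rank design required (rank deficiency raises, naming the
dependent columns); convergence is declared on relative coefficient change
below ``tol`` (default 1e-10) within ``max_iter`` Newton steps with
step-halving on deviance increase.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "GlmError",
    "SeparationError",
    "RankDeficiencyError",
    "ConvergenceError",
    "GlmFit",
    "fit_logistic",
    "fit_poisson",
]

_MAX_ETA = 500.0  # exp overflow guard on the log/logit scale


class GlmError(RuntimeError):
    pass


class SeparationError(GlmError):
    """Perfect separation in the logistic sampling model.

    The MLE does not exist; coarsen the covariate specification (fewer
    spline columns, pooled categories) rather than penalizing, which would
    silently change the estimand.
    """


class RankDeficiencyError(GlmError):
    def __init__(self, dropped: list[str]):
        self.dropped = dropped
        super().__init__(
            f"design matrix is rank deficient; dependent columns: {dropped}"
        )


class ConvergenceError(GlmError):
    pass


class GlmFit:
    """Coefficients plus model-based and robust (sandwich) covariances."""

    __slots__ = ("params", "cov_model", "cov_robust", "fitted", "converged", "names")

    def __init__(self, params, cov_model, cov_robust, fitted, converged, names):
        self.params = params
        self.cov_model = cov_model
        self.cov_robust = cov_robust
        self.fitted = fitted
        self.converged = converged
        self.names = names

    def se(self, robust: bool = True) -> np.ndarray:
        cov = self.cov_robust if robust else self.cov_model
        return np.sqrt(np.diag(cov))


def _check_rank(X: np.ndarray, names) -> None:
    if X.shape[0] < X.shape[1]:
        raise RankDeficiencyError(list(names) if names else ["<more columns than rows>"])
    _, rmat = np.linalg.qr(X, mode="reduced")
    diag = np.abs(np.diag(rmat))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps if diag.size else 0.0
    if (diag <= tol).any():
        bad = np.where(diag <= tol)[0]
        labels = [names[i] if names else str(i) for i in bad]
        raise RankDeficiencyError(labels)


def _solve_newton(X, step_score_info, deviance, beta0, tol, max_iter):
    beta = beta0.copy()
    dev = deviance(beta)
    for _ in range(max_iter):
        score, info = step_score_info(beta)
        try:
            delta = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            delta = np.linalg.lstsq(info, score, rcond=None)[0]
        step = 1.0
        for _half in range(30):
            cand = beta + step * delta
            cand_dev = deviance(cand)
            if cand_dev <= dev + 1e-12:
                break
            step *= 0.5
        else:
            return beta, False
        moved = np.max(np.abs(cand - beta)) / (1.0 + np.max(np.abs(cand)))
        beta, dev = cand, cand_dev
        if moved < tol:
            return beta, True
    return beta, False


def fit_logistic(
    X: np.ndarray,
    y: np.ndarray,
    *,
    names=None,
    start: np.ndarray | None = None,
    tol: float = 1e-10,
    max_iter: int = 100,
) -> GlmFit:
    """Maximum-likelihood logistic regression of a binary y on X.

    Raises :class:`SeparationError` when the fitted probabilities collapse to
    0/1 on both classes (perfect separation) and :class:`RankDeficiencyError`
    for a singular design.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    _check_rank(X, names)

    def eta_of(beta):
        return np.clip(X @ beta, -_MAX_ETA, _MAX_ETA)

    def deviance(beta):
        eta = eta_of(beta)
        # -2 loglik up to a constant, numerically stable log(1+e^eta)
        return float(2.0 * np.sum(np.logaddexp(0.0, eta) - y * eta))

    def step(beta):
        eta = eta_of(beta)
        p = 1.0 / (1.0 + np.exp(-eta))
        w = np.maximum(p * (1.0 - p), 1e-300)
        score = X.T @ (y - p)
        info = (X * w[:, None]).T @ X
        return score, info

    if start is not None:
        beta0 = np.asarray(start, float).copy()
    else:
        beta0 = np.zeros(X.shape[1])
        ybar = min(max(y.mean(), 1e-8), 1 - 1e-8)
        if names and names[0] == "intercept":
            beta0[0] = np.log(ybar / (1 - ybar))
    beta, converged = _solve_newton(X, step, deviance, beta0, tol, max_iter)

    eta = eta_of(beta)
    p = 1.0 / (1.0 + np.exp(-eta))
    # separation: fitted values numerically 0/1 wherever the class dictates
    eps = 1e-8
    if np.all((p > 1 - eps) | (y == 0)) and np.all((p < eps) | (y == 1)) and (
        np.any(p > 1 - eps) or np.any(p < eps)
    ):
        raise SeparationError(
            "perfect separation: sampled and unsampled municipalities are "
            "completely divided by the covariates; coarsen the covariate spec"
        )
    if not converged:
        raise ConvergenceError("logistic fit did not converge")

    w = np.maximum(p * (1.0 - p), 1e-300)
    info = (X * w[:, None]).T @ X
    cov_model = np.linalg.inv(info)
    resid = y - p
    meat = (X * (resid**2)[:, None]).T @ X
    cov_robust = cov_model @ meat @ cov_model
    return GlmFit(beta, cov_model, cov_robust, p, converged, names)


def fit_poisson(
    X: np.ndarray,
    y: np.ndarray,
    offset: np.ndarray,
    *,
    weights: np.ndarray | None = None,
    names=None,
    start: np.ndarray | None = None,
    tol: float = 1e-10,
    max_iter: int = 100,
) -> GlmFit:
    """(Weighted) Poisson regression with a log link and fixed offset.

    ``weights`` are analytic case weights (inverse sampling probabilities):
    they multiply each observation's log-likelihood contribution.  The robust
    covariance is the weighted sandwich, treating the weights as known.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    offset = np.asarray(offset, float)
    w = np.ones_like(y) if weights is None else np.asarray(weights, float)
    _check_rank(X * np.sqrt(w)[:, None], names)

    def mu_of(beta):
        return np.exp(np.clip(offset + X @ beta, -_MAX_ETA, _MAX_ETA))

    def deviance(beta):
        mu = mu_of(beta)
        with np.errstate(divide="ignore", invalid="ignore"):
            term = np.where(y > 0, y * np.log(y / mu), 0.0)
        return float(2.0 * np.sum(w * (term - (y - mu))))

    def step(beta):
        mu = mu_of(beta)
        score = X.T @ (w * (y - mu))
        info = (X * (w * mu)[:, None]).T @ X
        return score, info

    if start is not None:
        beta0 = np.asarray(start, float).copy()
    else:
        beta0 = np.zeros(X.shape[1])
        if names and names[0] == "intercept":
            tot_y = float(np.sum(w * y))
            tot_mu0 = float(np.sum(w * np.exp(np.clip(offset, -_MAX_ETA, _MAX_ETA))))
            if tot_y > 0 and tot_mu0 > 0:
                beta0[0] = np.log(tot_y / tot_mu0)
    beta, converged = _solve_newton(X, step, deviance, beta0, tol, max_iter)
    if not converged:
        raise ConvergenceError("Poisson fit did not converge")

    mu = mu_of(beta)
    info = (X * (w * mu)[:, None]).T @ X
    cov_model = np.linalg.inv(info)
    u = w * (y - mu)
    meat = (X * (u**2)[:, None]).T @ X
    cov_robust = cov_model @ meat @ cov_model
    return GlmFit(beta, cov_model, cov_robust, mu, converged, names)
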