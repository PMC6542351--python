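"""Sampling (selection) model, inverse-probability weights, and design diagnostics.

Municipalities enter the study through a mix of purposive and random
selection, so sampled and unsampled municipalities differ systematically.
Under conditional exchangeability given the contextual covariates Z, a
logistic model for Pr(S=1 | Z) — with continuous covariates expanded by
restricted quadratic splines — yields inverse-probability-of-sampling
weights W_i = 1 / Pr(S_i=1 | Z_i) that reweight the sampled municipalities
to represent the whole country.  Two diagnostics accompany the fit: a
covariate balance table (sampled vs. all municipalities) and a positivity
table that cross-classifies covariate strata and flags strata containing
municipalities but no sampled ones, where the weighting assumption fails by
construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from . import _glm
from .data import CovariateSpec, MunicipalityTable, ValidationError
from .splines import build_design

__all__ = [
    "SamplingFit",
    "PositivityTable",
    "fit_sampling_model",
    "compute_weights",
    "positivity_table",
    "balance_table",
]


@dataclass
class SamplingFit:
    """A fitted sampling model.

    ``fitted_prob`` covers every municipality (row order of the table);
    ``weights`` covers the sampled municipalities only, in table row order.
    """

    coefficients: np.ndarray
    design_columns: list[str]
    fitted_prob: np.ndarray
    weights: np.ndarray
    converged: bool
    cov_robust: np.ndarray | None = None
    #: the expanded design matrix over all municipalities; needed by the
    #: estimated-weights variance correction downstream
    design: np.ndarray | None = None

    @property
    def weight_sum(self) -> float:
        """Sum of the sampled weights; estimates the number of municipalities."""
        return float(self.weights.sum())


def fit_sampling_model(table: MunicipalityTable, spec: CovariateSpec) -> SamplingFit:
    """Fit Pr(sampled | Z) by maximum-likelihood logistic regression.

    Continuous covariates are spline-expanded (knots from the full country).
    Raises loudly on perfect separation or a rank-deficient design; both are
    signals to coarsen the covariate specification, not to penalize.
    """
    df = table.frame
    s = df["sampled"].to_numpy(dtype=float)
    if s.min() == s.max():
        raise ValidationError(
            "sampling model needs both sampled and unsampled municipalities"
        )
    X, names = build_design(df, spec)
    fit = _glm.fit_logistic(X, s, names=names)
    p = fit.fitted
    weights = 1.0 / p[s == 1]
    return SamplingFit(
        coefficients=fit.params,
        design_columns=names,
        fitted_prob=p,
        weights=weights,
        converged=fit.converged,
        cov_robust=fit.cov_robust,
        design=X,
    )


def compute_weights(fit: SamplingFit, table: MunicipalityTable) -> np.ndarray:
    """Inverse-probability weights W_i = 1/p_i for the sampled rows only."""
    if not fit.converged:
        raise _glm.ConvergenceError("sampling model did not converge; no weights")
    mask = table.sampled_mask
    p = fit.fitted_prob[mask]
    if np.any(p <= 0):
        raise ValidationError("fitted sampling probability is zero for a sampled row")
    return 1.0 / p


@dataclass
class PositivityTable:
    """Cross-classified sampling-probability diagnostic.

    ``frame`` has one row per stratum with columns ``stratum`` (label),
    ``n`` (municipalities), ``n_sampled`` and ``prop_sampled``;
    ``empty_strata`` lists strata containing municipalities but none sampled
    — the direct, designed check of the positivity assumption.
    """

    frame: pd.DataFrame
    empty_strata: list[str] = field(default_factory=list)

    @property
    def violated(self) -> bool:
        return len(self.empty_strata) > 0


def _bin_column(
    x: np.ndarray, rule, name: str
) -> tuple[np.ndarray, list[str]]:
    """Bin one covariate by explicit edges or an integer quantile count."""
    if isinstance(rule, int):
        qs = np.quantile(x, np.linspace(0, 1, rule + 1))
        edges = np.unique(qs)
    else:
        edges = np.asarray(list(rule), dtype=float)
    if len(edges) < 2:
        raise ValidationError(f"cannot bin constant covariate {name!r}")
    if x.min() < edges[0] or x.max() > edges[-1]:
        raise ValidationError(
            f"covariate {name!r} has values outside the provided bins"
        )
    idx = np.clip(np.searchsorted(edges, x, side="right") - 1, 0, len(edges) - 2)
    labels = [
        f"{name}[{edges[j]:.4g},{edges[j + 1]:.4g}]" for j in range(len(edges) - 1)
    ]
    return idx, labels


def positivity_table(
    table: MunicipalityTable,
    binning: Mapping[str, object] | None = None,
) -> PositivityTable:
    """Sampling proportions within cross-classified covariate strata.

    ``binning`` maps covariate name -> either an integer (that many quantile
    bins) or explicit ascending bin edges covering the observed range.  The
    default mirrors the usual field diagnostic: population-density tertiles
    crossed with poverty tertiles.
    """
    if binning is None:
        binning = {}
        for c in ("log_density", "poverty"):
            if c in table.covariate_columns:
                binning[c] = 3
        if not binning:
            # fall back to the first continuous-looking covariate
            c = table.covariate_columns[0]
            binning = {c: 3}
    df = table.frame
    idx_parts, label_parts = [], []
    for name, rule in binning.items():
        if name not in df.columns:
            raise ValidationError(f"binning covariate {name!r} not in table")
        idx, labels = _bin_column(df[name].to_numpy(dtype=float), rule, name)
        idx_parts.append(idx)
        label_parts.append(labels)

    # enumerate occupied cells of the cross-classification
    key = np.stack(idx_parts, axis=1)
    rows = []
    empty: list[str] = []
    seen = sorted({tuple(r) for r in key})
    for cell in seen:
        mask = np.all(key == np.array(cell), axis=1)
        label = " x ".join(
            label_parts[d][cell[d]] for d in range(len(label_parts))
        )
        n = int(mask.sum())
        n_s = int(df.loc[mask, "sampled"].sum())
        rows.append(
            {"stratum": label, "n": n, "n_sampled": n_s, "prop_sampled": n_s / n}
        )
        if n > 0 and n_s == 0:
            empty.append(label)
    frame = pd.DataFrame(rows)
    return PositivityTable(frame=frame, empty_strata=empty)


def balance_table(table: MunicipalityTable, spec: CovariateSpec) -> pd.DataFrame:
    """Covariate means among all municipalities vs. the sampled subset.

    Returns a frame with ``mean_all``, ``mean_sampled`` and the standardized
    difference (mean_sampled - mean_all) / pooled SD, where the pooled SD is
    the root mean square of the two group SDs.  A zero-variance covariate
    gets a missing standardized difference rather than a NaN cascade.
    """
    df = table.frame
    mask = table.sampled_mask
    if mask.sum() == 0:
        raise ValidationError("balance table needs at least one sampled municipality")
    rows = []
    for c in spec.covariates:
        x = df[c].to_numpy(dtype=float)
        xs = x[mask]
        sd_all = float(np.std(x, ddof=1)) if len(x) > 1 else 0.0
        sd_s = float(np.std(xs, ddof=1)) if len(xs) > 1 else 0.0
        pooled = np.sqrt((sd_all**2 + sd_s**2) / 2.0)
        diff = float(xs.mean() - x.mean())
        std_diff = diff / pooled if pooled > 0 else pd.NA
        rows.append(
            {
                "covariate": c,
                "mean_all": float(x.mean()),
                "mean_sampled": float(xs.mean()),
                "std_diff": std_diff,
            }
        )
    out = pd.DataFrame(rows).set_index("covariate")
    out["std_diff"] = pd.array(out["std_diff"], dtype="Float64")
    return out
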