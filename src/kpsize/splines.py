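"""Restricted quadratic spline bases and design-matrix construction.

Continuous contextual covariates enter the sampling and outcome models through
flexible functional forms: a linear term plus a restricted quadratic spline
basis.  With knots ``t_1 < ... < t_K`` the j-th basis column (j = 1..K-1) at a
point x is

    [ (x - t_j)_+^2 - (x - t_K)_+^2 ] / (t_K - t_1)

which is zero left of the first knot, piecewise quadratic between knots, and
exactly linear beyond the last knot (the quadratic pieces cancel), so the
fitted curve cannot bend wildly in the tails.  Dividing by the knot span keeps
the columns on the scale of x itself, which conditions the GLM solves; any
full-rank linear reparameterization gives identical fitted values.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .data import CovariateSpec

__all__ = ["SplineBasis", "restricted_quadratic_basis", "default_knots", "build_design"]


@dataclass(frozen=True)
class SplineBasis:
    knots: np.ndarray
    values: np.ndarray  # (n, K-1)

    @property
    def n_columns(self) -> int:
        return self.values.shape[1]


def restricted_quadratic_basis(x, knots) -> SplineBasis:
    """Evaluate the restricted quadratic spline basis at the points ``x``.

    Raises ``ValueError`` for fewer than two knots or non-ascending knots.
    """
    x = np.asarray(x, dtype=float)
    knots = np.asarray(knots, dtype=float)
    if knots.ndim != 1 or len(knots) < 2:
        raise ValueError("restricted quadratic splines need at least 2 knots")
    if not np.all(np.diff(knots) > 0):
        raise ValueError("knots must be strictly ascending")
    span = knots[-1] - knots[0]
    last = np.clip(x - knots[-1], 0.0, None) ** 2
    cols = [
        (np.clip(x - t, 0.0, None) ** 2 - last) / span
        for t in knots[:-1]
    ]
    return SplineBasis(knots=knots, values=np.column_stack(cols))


def _percentiles_sorted(xs: np.ndarray, qs: np.ndarray) -> np.ndarray:
    """Linear-interpolation percentiles of an already-sorted array.

    Same definition as ``np.percentile(..., method="linear")`` but without
    its dispatch overhead, which matters inside the bootstrap loops.
    """
    pos = qs / 100.0 * (len(xs) - 1)
    lo = np.floor(pos).astype(int)
    hi = np.minimum(lo + 1, len(xs) - 1)
    frac = pos - lo
    return xs[lo] * (1.0 - frac) + xs[hi] * frac


def default_knots(x, n_knots: int = 3) -> np.ndarray:
    """Knots at equally spaced percentiles of x (5th..95th).

    For 3 knots these are the 5th/50th/95th percentiles (linear-interpolation
    definition).  Duplicate percentile values are collapsed; if fewer than two
    distinct knots remain the covariate cannot support a spline and a
    ``ValueError`` is raised.
    """
    x = np.asarray(x, dtype=float)
    if n_knots < 2:
        raise ValueError("need at least 2 knots")
    qs = np.linspace(5.0, 95.0, n_knots)
    knots = np.unique(_percentiles_sorted(np.sort(x), qs))
    if len(knots) < 2:
        raise ValueError("too few distinct values to place knots")
    return knots


def build_design(
    frame: pd.DataFrame | Mapping[str, np.ndarray],
    spec: CovariateSpec,
    *,
    intercept: bool = True,
) -> tuple[np.ndarray, list[str]]:
    """Expand a covariate frame into a model design matrix.

    Each continuous covariate contributes its linear term plus the restricted
    quadratic spline columns for knots placed on the *full* frame passed in
    (so a model fit on the sampled subset of rows shares the basis used to
    predict all rows).  A continuous covariate with fewer distinct values
    than ``spec.min_distinct_for_spline`` falls back to its linear term only.
    Binary/other covariates enter linearly.  Returns the matrix and column
    names (``"x_rq1"`` etc. for spline columns).

    ``frame`` may be a DataFrame or a plain mapping of column name to float
    array (the fast path used by the bootstrap loops).
    """
    is_frame = isinstance(frame, pd.DataFrame)
    columns = frame.columns if is_frame else frame.keys()
    spec.validate_against(columns)
    n = len(frame) if is_frame else len(next(iter(frame.values())))
    cols: list[np.ndarray] = []
    names: list[str] = []
    if intercept:
        cols.append(np.ones(n))
        names.append("intercept")
    for c in spec.covariates:
        x = frame[c].to_numpy(dtype=float) if is_frame else frame[c]
        cols.append(x)
        names.append(c)
        if c in spec.continuous and len(np.unique(x)) >= spec.min_distinct_for_spline:
            try:
                knots = default_knots(x, spec.n_knots)
            except ValueError:
                continue  # degenerate distribution: linear term only
            if len(knots) >= 2:
                basis = restricted_quadratic_basis(x, knots)
                for j in range(basis.n_columns):
                    cols.append(basis.values[:, j])
                    names.append(f"{c}_rq{j + 1}")
    return np.column_stack(cols), names
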