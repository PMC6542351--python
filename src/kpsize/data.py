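"""Municipality-level data model and I/O.

The unit of analysis is the municipality: each row carries a denominator
population ``denom`` (the number of people who could belong to the key
population, e.g. women aged 15-49 for female sex workers), a binary sampling
indicator ``sampled``, a direct-estimate count ``count`` that is present if
and only if the municipality was sampled, and a set of contextual covariates
observed for *every* municipality (population density, poverty, tourism, HIV
prevalence, ...).  Missingness of ``count`` is the core semantics of the whole
package, so it is validated strictly: an absent count is an empty CSV cell,
never a numeric sentinel.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ValidationError",
    "CovariateSpec",
    "MunicipalityTable",
    "TruthTable",
    "SizeEstimate",
    "FSW_SPEC",
    "MSM_SPEC",
    "TGW_SPEC",
    "read_municipality_table",
    "write_estimates",
    "read_estimates",
]

#: columns every municipality table must provide, in canonical order
REQUIRED_COLUMNS = ("municipality_id", "province_id", "denom", "sampled", "count")

#: extra columns carried only by synthetic truth tables
TRUTH_COLUMNS = ("true_count", "true_pi", "sampling_stage")


class ValidationError(ValueError):
    """A municipality table violated one of its invariants.

    The message always names the offending municipality or column so the
    problem can be traced back to the input file.
    """


@dataclass(frozen=True)
class CovariateSpec:
    """Which contextual covariates enter the sampling and outcome models.

    Parameters
    ----------
    population
        Label for the key population this spec belongs to (``"fsw"``,
        ``"msm"``, ``"tgw"``, or any custom label).
    covariates
        All covariate column names used by the models.
    continuous
        The subset of ``covariates`` expanded with restricted quadratic
        spline bases; the rest enter linearly (typically binary indicators).
    n_knots
        Knots per continuous covariate, placed at equally spaced percentiles
        (5th/50th/95th for the default of 3).
    min_distinct_for_spline
        A continuous covariate with fewer distinct observed values than this
        falls back to a single linear term, which keeps small-sample designs
        full rank.
    """

    population: str
    covariates: tuple[str, ...]
    continuous: tuple[str, ...] = ()
    n_knots: int = 3
    min_distinct_for_spline: int = 25

    def __post_init__(self) -> None:
        unknown = set(self.continuous) - set(self.covariates)
        if unknown:
            raise ValidationError(
                f"continuous covariates {sorted(unknown)} not listed in covariates"
            )

    @property
    def binary(self) -> tuple[str, ...]:
        """Covariates entering the design linearly (not spline-expanded)."""
        return tuple(c for c in self.covariates if c not in self.continuous)

    def validate_against(self, columns: Iterable[str]) -> None:
        missing = set(self.covariates) - set(columns)
        if missing:
            raise ValidationError(
                f"covariates {sorted(missing)} not present in table columns"
            )

    def drop(self, *names: str) -> "CovariateSpec":
        """A copy of the spec without the named covariates (for
        misspecification experiments)."""
        keep = tuple(c for c in self.covariates if c not in names)
        cont = tuple(c for c in self.continuous if c not in names)
        return dataclasses.replace(self, covariates=keep, continuous=cont)

    def linear_only(self) -> "CovariateSpec":
        """A copy with no spline expansion (all covariates enter linearly)."""
        return dataclasses.replace(self, continuous=())


# Default covariate rosters.  All populations share population density (on the
# log scale), poverty, tourism and general-population HIV prevalence; the FSW
# roster adds adolescent pregnancy, female education and border/port presence,
# while the MSM/TGW rosters add university presence.
FSW_SPEC = CovariateSpec(
    population="fsw",
    covariates=(
        "log_density",
        "poverty",
        "tourism",
        "hiv_prev",
        "adolescent_pregnancy",
        "education_years",
        "border_port",
    ),
    continuous=(
        "log_density",
        "poverty",
        "hiv_prev",
        "adolescent_pregnancy",
        "education_years",
    ),
)

MSM_SPEC = CovariateSpec(
    population="msm",
    covariates=("log_density", "poverty", "tourism", "hiv_prev", "university"),
    continuous=("log_density", "poverty", "hiv_prev"),
)

TGW_SPEC = CovariateSpec(
    population="tgw",
    covariates=("log_density", "poverty", "tourism", "hiv_prev", "university"),
    continuous=("log_density", "poverty", "hiv_prev"),
)

DEFAULT_SPECS: Mapping[str, CovariateSpec] = {
    "fsw": FSW_SPEC,
    "msm": MSM_SPEC,
    "tgw": TGW_SPEC,
}


def _validate_frame(df: pd.DataFrame, *, require_count_pattern: bool = True) -> None:
    """Run all MunicipalityTable invariants on a raw frame; raise on the first
    violation, naming the offending row."""
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise ValidationError(f"required column {col!r} is missing")

    ids = df["municipality_id"]
    dup = ids[ids.duplicated()]
    if len(dup):
        raise ValidationError(f"duplicate municipality_id {dup.iloc[0]!r}")

    denom = pd.to_numeric(df["denom"], errors="coerce")
    if denom.isna().any():
        bad = df.loc[denom.isna(), "municipality_id"].iloc[0]
        raise ValidationError(f"non-numeric denom for municipality {bad!r}")
    if (denom <= 0).any():
        bad = df.loc[denom <= 0, "municipality_id"].iloc[0]
        raise ValidationError(f"denom must be positive; municipality {bad!r}")

    sampled = df["sampled"]
    if not sampled.isin([0, 1]).all():
        bad = df.loc[~sampled.isin([0, 1]), "municipality_id"].iloc[0]
        raise ValidationError(f"sampled must be 0/1; municipality {bad!r}")

    count = pd.to_numeric(df["count"], errors="coerce")
    has_raw = df["count"].notna()
    bad_numeric = has_raw & count.isna()
    if bad_numeric.any():
        bad = df.loc[bad_numeric, "municipality_id"].iloc[0]
        raise ValidationError(f"non-numeric count for municipality {bad!r}")

    if require_count_pattern:
        miss_sampled = (sampled == 1) & ~has_raw
        if miss_sampled.any():
            bad = df.loc[miss_sampled, "municipality_id"].iloc[0]
            raise ValidationError(
                f"sampled municipality {bad!r} has no direct-estimate count"
            )
        present_unsampled = (sampled == 0) & has_raw
        if present_unsampled.any():
            bad = df.loc[present_unsampled, "municipality_id"].iloc[0]
            raise ValidationError(
                f"unsampled municipality {bad!r} carries a count value; "
                "missing counts must be empty cells, not sentinels"
            )

    neg = count < 0
    if neg.any():
        bad = df.loc[neg, "municipality_id"].iloc[0]
        raise ValidationError(f"negative count for municipality {bad!r}")
    over = count > denom
    if over.fillna(False).any():
        bad = df.loc[over.fillna(False), "municipality_id"].iloc[0]
        raise ValidationError(
            f"count exceeds denominator for municipality {bad!r}"
        )

    covariate_cols = [
        c
        for c in df.columns
        if c not in REQUIRED_COLUMNS and c not in TRUTH_COLUMNS
    ]
    for c in covariate_cols:
        vals = pd.to_numeric(df[c], errors="coerce")
        if vals.isna().any():
            bad = df.loc[vals.isna(), "municipality_id"].iloc[0]
            raise ValidationError(
                f"covariate {c!r} missing or non-numeric for municipality {bad!r}"
            )


@dataclass
class MunicipalityTable:
    """A validated country: one row per municipality.

    Wraps a :class:`pandas.DataFrame` with the canonical columns
    ``municipality_id, province_id, denom, sampled, count`` plus one column
    per contextual covariate.  ``count`` is NaN exactly on unsampled rows.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.frame.reset_index(drop=True).copy()
        _validate_frame(df, require_count_pattern=self._require_count_pattern())
        df["municipality_id"] = df["municipality_id"].astype(str)
        df["province_id"] = df["province_id"].astype(str)
        df["denom"] = df["denom"].astype(float)
        df["sampled"] = df["sampled"].astype(int)
        df["count"] = pd.to_numeric(df["count"], errors="coerce").astype(float)
        self.frame = df

    @staticmethod
    def _require_count_pattern() -> bool:
        return True

    # -- basic accessors ---------------------------------------------------
    @property
    def covariate_columns(self) -> tuple[str, ...]:
        return tuple(
            c
            for c in self.frame.columns
            if c not in REQUIRED_COLUMNS and c not in TRUTH_COLUMNS
        )

    @property
    def n_total(self) -> int:
        return len(self.frame)

    @property
    def n_sampled(self) -> int:
        return int(self.frame["sampled"].sum())

    @property
    def sampled_mask(self) -> np.ndarray:
        return self.frame["sampled"].to_numpy() == 1

    @property
    def denom_total(self) -> float:
        return float(self.frame["denom"].sum())

    def __len__(self) -> int:  # pragma: no cover - trivial
        return len(self.frame)

    def equals(self, other: "MunicipalityTable") -> bool:
        a = self.frame[list(self.frame.columns)]
        b = other.frame[list(self.frame.columns)]
        try:
            pd.testing.assert_frame_equal(a, b, check_dtype=False)
        except AssertionError:
            return False
        return True

    # -- I/O ---------------------------------------------------------------
    def to_csv(self, path: str | Path) -> None:
        """Write the table as UTF-8 CSV; absent counts become empty cells."""
        self.frame.to_csv(path, index=False)


class TruthTable(MunicipalityTable):
    """A synthetic country that also carries its hidden ground truth.

    Adds ``true_count`` and ``true_pi`` for every municipality and the
    ``sampling_stage`` label (``purposive``/``random``/``none``).  Observed
    counts equal the true counts wherever ``sampled == 1``.
    """

    def __post_init__(self) -> None:
        super().__post_init__()
        df = self.frame
        for col in TRUTH_COLUMNS:
            if col not in df.columns:
                raise ValidationError(f"truth table missing column {col!r}")
        s = df["sampled"] == 1
        if not np.allclose(df.loc[s, "count"], df.loc[s, "true_count"]):
            raise ValidationError("observed count differs from true_count on a sampled row")

    @property
    def pi_true(self) -> float:
        """Realized national proportion: total true count over total denominator."""
        return float(self.frame["true_count"].sum() / self.frame["denom"].sum())

    def to_observed(self) -> MunicipalityTable:
        """Strip the hidden truth columns, leaving an analysis table."""
        cols = [c for c in self.frame.columns if c not in TRUTH_COLUMNS]
        return MunicipalityTable(self.frame[cols].copy())


@dataclass
class SizeEstimate:
    """A method-labelled national size estimate.

    ``pi_hat`` is the estimated national proportion (raw scale; multiply by
    100 only for display), ``log_se`` the standard error of log pi_hat, and
    ``national_count`` the implied number of key population members,
    ``pi_hat`` times the national denominator.
    """

    method: str
    pi_hat: float
    log_se: float
    ci_low: float
    ci_high: float
    national_count: float
    n_total: int
    n_sampled: int
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0 < self.pi_hat < 1):
            raise ValidationError(f"pi_hat {self.pi_hat} outside (0, 1)")
        if self.log_se < 0 or not math.isfinite(self.log_se):
            raise ValidationError(f"log_se {self.log_se} must be a nonnegative real")
        if not (0 < self.ci_low <= self.pi_hat <= self.ci_high):
            raise ValidationError(
                f"interval ({self.ci_low}, {self.ci_high}) does not bracket {self.pi_hat}"
            )

    def scaled_interval(self, denom_total: float) -> tuple[float, float]:
        """The CI on the national-count scale (endpoints scale linearly)."""
        return self.ci_low * denom_total, self.ci_high * denom_total


def read_municipality_table(
    path: str | Path,
    spec: CovariateSpec | None = None,
    *,
    coerce_unsampled_counts: bool = False,
) -> MunicipalityTable:
    """Read and validate a municipality CSV.

    Parameters
    ----------
    path
        CSV with header row and columns ``municipality_id, province_id,
        denom, sampled, count, <covariates...>``; absent counts are empty
        cells.
    spec
        Optional covariate spec; when given, its covariates are checked to be
        present in the file.
    coerce_unsampled_counts
        When True, a numeric count on an unsampled row is silently blanked
        instead of raising.  Off by default: sentinel-coded missingness is an
        input error.
    """
    df = pd.read_csv(path, dtype={"municipality_id": str, "province_id": str})
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise ValidationError(f"required column {col!r} is missing from {path}")
    if coerce_unsampled_counts:
        df.loc[df["sampled"] == 0, "count"] = np.nan
    table = MunicipalityTable(df)
    if spec is not None:
        spec.validate_against(table.frame.columns)
    return table


def read_truth_table(path: str | Path) -> TruthTable:
    """Read a synthetic truth table written by :meth:`TruthTable.to_csv`."""
    df = pd.read_csv(path, dtype={"municipality_id": str, "province_id": str})
    return TruthTable(df)


def write_estimates(
    estimates: Sequence[SizeEstimate],
    path: str | Path,
    *,
    sidecar: bool = True,
) -> None:
    """Write estimates as CSV (full float precision) plus a JSON metadata sidecar.

    The CSV holds one row per estimate with columns ``method, pi_hat, log_se,
    ci_low, ci_high, national_count, n_total, n_sampled``; the sidecar
    ``<path>.json`` records each estimate's settings (imputations, bootstrap
    replicates, seed, model coefficients where applicable).
    """
    if not estimates:
        raise ValueError("write_estimates requires a nonempty list of estimates")
    path = Path(path)
    rows = []
    for est in estimates:
        rows.append(
            {
                "method": est.method,
                "pi_hat": repr(est.pi_hat),
                "log_se": repr(est.log_se),
                "ci_low": repr(est.ci_low),
                "ci_high": repr(est.ci_high),
                "national_count": repr(est.national_count),
                "n_total": est.n_total,
                "n_sampled": est.n_sampled,
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)
    if sidecar:
        meta = {est.method: _jsonable(est.meta) for est in estimates}
        Path(str(path) + ".json").write_text(json.dumps(meta, indent=2))


def read_estimates(path: str | Path) -> list[SizeEstimate]:
    df = pd.read_csv(path, float_precision="round_trip")
    out = []
    for _, row in df.iterrows():
        out.append(
            SizeEstimate(
                method=str(row["method"]),
                pi_hat=float(row["pi_hat"]),
                log_se=float(row["log_se"]),
                ci_low=float(row["ci_low"]),
                ci_high=float(row["ci_high"]),
                national_count=float(row["national_count"]),
                n_total=int(row["n_total"]),
                n_sampled=int(row["n_sampled"]),
            )
        )
    return out


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj
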