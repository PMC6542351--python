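"""Model/Results interface over the four estimators.

`KeyPopulationModel` holds a validated municipality table and a covariate
specification; its ``fit`` dispatches to the estimator functions and returns
a `SizeResults` carrying the estimates, their log-scale standard errors,
95% intervals, implied national counts, and design diagnostics.  The
functions in :mod:`kpsize.estimators` remain the primitive interface; this
class is the convenient front door.

Example
-------
>>> from kpsize import KeyPopulationModel, dr_like_fixture
>>> table = dr_like_fixture(seed=1).to_observed()
>>> model = KeyPopulationModel(table, population="fsw")
>>> res = model.fit(method="all", seed=1, bootstrap=200, imputations=20)
>>> print(res.summary())          # doctest: +SKIP
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .data import (
    DEFAULT_SPECS,
    CovariateSpec,
    MunicipalityTable,
    SizeEstimate,
    write_estimates,
)
from .estimators import (
    estimate_aipw,
    estimate_complete_case,
    estimate_ipsw,
    estimate_mi,
)
from .sampling import balance_table, fit_sampling_model, positivity_table

__all__ = ["KeyPopulationModel", "SizeResults"]

_METHOD_ALIASES = {
    "cc": "complete_case",
    "complete_case": "complete_case",
    "ipsw": "ipsw",
    "mi": "mi",
    "aipw": "aipw",
}


class KeyPopulationModel:
    """National key population size estimation for one country table.

    Parameters
    ----------
    table
        A validated :class:`MunicipalityTable`.
    covariates
        A :class:`CovariateSpec`, or None to use the packaged default for
        ``population``.
    population
        Key population label (``"fsw"``, ``"msm"``, ``"tgw"``); selects the
        default covariate roster when ``covariates`` is None.
    """

    def __init__(
        self,
        table: MunicipalityTable,
        covariates: CovariateSpec | None = None,
        population: str = "fsw",
    ):
        if covariates is None:
            if population not in DEFAULT_SPECS:
                raise ValueError(
                    f"no default covariate spec for population {population!r}"
                )
            covariates = DEFAULT_SPECS[population]
        covariates.validate_against(table.frame.columns)
        self.table = table
        self.spec = covariates

    @classmethod
    def from_dataframe(
        cls,
        frame: pd.DataFrame,
        covariates: CovariateSpec | Sequence[str] | None = None,
        population: str = "fsw",
        continuous: Sequence[str] | None = None,
    ) -> "KeyPopulationModel":
        """Build the model straight from a raw DataFrame.

        ``covariates`` may be a spec or a plain list of column names (with
        ``continuous`` naming the spline-expanded subset; defaults to all of
        them).
        """
        table = MunicipalityTable(frame)
        if covariates is not None and not isinstance(covariates, CovariateSpec):
            names = tuple(covariates)
            cont = tuple(continuous) if continuous is not None else names
            covariates = CovariateSpec(
                population=population, covariates=names, continuous=cont
            )
        return cls(table, covariates=covariates, population=population)

    def fit(
        self,
        method: str = "aipw",
        *,
        imputations: int = 50,
        bootstrap: int = 1000,
        seed: int | None = None,
    ) -> "SizeResults":
        """Estimate the national proportion.

        ``method`` is one of ``cc``/``complete_case``, ``ipsw``, ``mi``,
        ``aipw`` or ``all``.  ``seed`` drives the MI coefficient draws and
        the AIPW bootstrap through independent substreams, so changing
        ``imputations`` or ``bootstrap`` does not couple the two.
        """
        ss = np.random.SeedSequence(seed)
        mi_seed, aipw_seed = ss.spawn(2)
        wanted = []
        for name in ([m for m in ("cc", "ipsw", "mi", "aipw")] if method == "all" else [method]):
            if name not in _METHOD_ALIASES:
                raise ValueError(f"unknown method {name!r}")
            wanted.append(_METHOD_ALIASES[name])
        estimates = []
        for name in wanted:
            if name == "complete_case":
                estimates.append(estimate_complete_case(self.table))
            elif name == "ipsw":
                estimates.append(estimate_ipsw(self.table, self.spec))
            elif name == "mi":
                estimates.append(
                    estimate_mi(
                        self.table,
                        self.spec,
                        M=imputations,
                        seed=np.random.default_rng(mi_seed),
                    )
                )
            else:
                estimates.append(
                    estimate_aipw(
                        self.table,
                        self.spec,
                        B=bootstrap,
                        seed=np.random.default_rng(aipw_seed),
                    )
                )
        return SizeResults(model=self, estimates=estimates)

    def diagnostics(self, binning=None):
        """Positivity table and covariate balance table for the design."""
        return (
            positivity_table(self.table, binning=binning),
            balance_table(self.table, self.spec),
        )

    def sampling_fit(self):
        return fit_sampling_model(self.table, self.spec)


@dataclass
class SizeResults:
    """Fitted national size estimates for one table."""

    model: KeyPopulationModel
    estimates: list[SizeEstimate] = field(default_factory=list)

    def __getitem__(self, method: str) -> SizeEstimate:
        method = _METHOD_ALIASES.get(method, method)
        for est in self.estimates:
            if est.method == method:
                return est
        raise KeyError(method)

    @property
    def pi_hat(self) -> float:
        """Point estimate of the first (or only) fitted method."""
        return self.estimates[0].pi_hat

    def conf_int(self, method: str | None = None) -> tuple[float, float]:
        est = self.estimates[0] if method is None else self[method]
        return est.ci_low, est.ci_high

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "method": e.method,
                "pi_hat": e.pi_hat,
                "log_se": e.log_se,
                "ci_low": e.ci_low,
                "ci_high": e.ci_high,
                "national_count": e.national_count,
            }
            for e in self.estimates
        ]
        return pd.DataFrame(rows).set_index("method")

    def save(self, path) -> None:
        write_estimates(self.estimates, path)

    def summary(self) -> str:
        """A printable table: percent scale for display, counts rounded."""
        pop = self.model.spec.population
        k, n_s = self.model.table.n_total, self.model.table.n_sampled
        lines = [
            f"National key population size estimates [{pop}]",
            f"municipalities: {k} total, {n_s} with direct estimates",
            f"national denominator: {self.model.table.denom_total:,.0f}",
            "",
            f"{'method':<14}{'pi_hat %':>10}{'95% CI %':>18}{'count':>12}",
        ]
        for e in self.estimates:
            ci = f"({100 * e.ci_low:.2f}, {100 * e.ci_high:.2f})"
            lines.append(
                f"{e.method:<14}{100 * e.pi_hat:>10.2f}{ci:>18}"
                f"{e.national_count:>12,.0f}"
            )
        return "\n".join(lines)

    def plot(self, ax=None):
        """Forest-style plot of the estimates (percent scale)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 0.8 + 0.6 * len(self.estimates)))
        ys = np.arange(len(self.estimates))[::-1]
        for y, e in zip(ys, self.estimates):
            ax.plot(
                [100 * e.ci_low, 100 * e.ci_high], [y, y], color="C0", lw=2
            )
            ax.plot([100 * e.pi_hat], [y], "o", color="C0")
        ax.set_yticks(ys)
        ax.set_yticklabels([e.method for e in self.estimates])
        ax.set_xlabel("national proportion (%)")
        ax.set_title(f"key population size [{self.model.spec.population}]")
        return ax
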