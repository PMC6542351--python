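"""Factorial simulation experiments: bias, RMSE, coverage, CI width.

Each replicate generates a fresh synthetic country, applies the requested
estimators, and records the error against that replicate's realized national
proportion.  The double-robustness suite runs the 2x2 grid of working-model
misspecification — {sampling model correct/incorrect} x {outcome model
correct/incorrect} — by omitting the scenario's key confounders from the
corresponding model specification, and reports all four estimators in every
cell.  Misspecification lives purely on the analysis side: the generated
countries in all four cells share the same generative law.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import _glm
from .data import CovariateSpec, ValidationError
from .estimators import (
    estimate_aipw,
    estimate_complete_case,
    estimate_ipsw,
    estimate_mi,
)
from .synthetic import Scenario, default_scenario, generate_country

__all__ = [
    "METHODS",
    "SimulationResult",
    "RobustnessGrid",
    "simulation_spec",
    "run_scenario",
    "double_robustness_suite",
    "render_report",
]

METHODS = ("cc", "ipsw", "mi", "aipw")

#: covariates the analysis models use in simulations (a compact subset of the
#: full roster keeps the outcome design well below the 50 sampled rows)
_SIM_COVARIATES = ("log_density", "poverty", "tourism", "hiv_prev")
_SIM_CONTINUOUS = ("log_density", "poverty", "hiv_prev")

#: the covariates omitted by the misspecification switches.  Omitting all of
#: them reduces the broken working model to intercept-only — the classic
#: crude model that ignores context entirely (the naive "apply the average
#: prevalence everywhere" approach).  Partial omission leaves the remaining
#: covariates proxying the omitted confounders, which dilutes the designed
#: misspecification; full omission makes the failure decisive.
OMITTED_KEY_COVARIATES = ("poverty", "log_density", "tourism", "hiv_prev")


def simulation_spec(
    population: str = "fsw",
    *,
    misspecified: bool = False,
    linear_only: bool = False,
) -> CovariateSpec:
    """The covariate spec the simulation's analysis models use.

    ``misspecified=True`` omits the key confounders (poverty and log
    density); ``linear_only=True`` drops the spline expansion (wrong
    functional form).
    """
    spec = CovariateSpec(
        population=population,
        covariates=_SIM_COVARIATES,
        continuous=_SIM_CONTINUOUS,
    )
    if misspecified:
        spec = spec.drop(*OMITTED_KEY_COVARIATES)
    if linear_only:
        spec = spec.linear_only()
    return spec


@dataclass
class SimulationResult:
    """Per-method operating characteristics over replicate countries."""

    scenario_label: str
    n_reps: int
    summary: pd.DataFrame  # indexed by method
    replicates: pd.DataFrame  # long: rep, method, pi_hat, ci_low, ci_high, pi_true

    def method_row(self, method: str) -> pd.Series:
        return self.summary.loc[method]


def _misspec_switches(misspecification) -> frozenset:
    if misspecification is None:
        return frozenset()
    if isinstance(misspecification, str):
        misspecification = (misspecification,)
    allowed = {
        "omit_covariate_in_sampling",
        "omit_covariate_in_outcome",
        "wrong_functional_form_sampling",
        "wrong_functional_form_outcome",
    }
    switches = frozenset(misspecification) - {"none"}
    unknown = switches - allowed
    if unknown:
        raise ValueError(f"unknown misspecification switches {sorted(unknown)}")
    return switches


def run_scenario(
    scenario: Scenario,
    methods: Sequence[str] = METHODS,
    n_reps: int = 500,
    seed: int = 0,
    M: int = 20,
    B: int = 200,
    misspecification=None,
    scenario_label: str | None = None,
) -> SimulationResult:
    """Run one simulation cell.

    Per replicate: generate a country from a spawned substream, compute every
    requested estimator, record the error against the replicate's realized
    national proportion.  Failed method evaluations are recorded and
    excluded from the summaries; a method with more than 10% failures is
    flagged invalid in its summary row.
    """
    if n_reps < 2:
        raise ValueError("need at least 2 replicates")
    bad = set(methods) - set(METHODS)
    if bad:
        raise ValueError(f"unknown methods {sorted(bad)}")
    switches = _misspec_switches(misspecification)
    sampling_spec = simulation_spec(
        scenario.population,
        misspecified="omit_covariate_in_sampling" in switches,
        linear_only="wrong_functional_form_sampling" in switches,
    )
    outcome_spec = simulation_spec(
        scenario.population,
        misspecified="omit_covariate_in_outcome" in switches,
        linear_only="wrong_functional_form_outcome" in switches,
    )

    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_reps)
    rows = []
    for rep, child in enumerate(children):
        gen_seed, method_seed = child.spawn(2)
        country = generate_country(scenario, seed=gen_seed)
        table = country.to_observed()
        pi_true = country.pi_true
        mi_seed, aipw_seed = method_seed.spawn(2)
        for method in methods:
            try:
                if method == "cc":
                    est = estimate_complete_case(table)
                elif method == "ipsw":
                    est = estimate_ipsw(table, sampling_spec)
                elif method == "mi":
                    est = estimate_mi(table, outcome_spec, M=M,
                                      seed=np.random.default_rng(mi_seed))
                else:
                    est = estimate_aipw(table, sampling_spec, B=B,
                                        seed=np.random.default_rng(aipw_seed),
                                        outcome_spec=outcome_spec)
            except (_glm.GlmError, ValidationError, RuntimeError,
                    np.linalg.LinAlgError):
                rows.append({"rep": rep, "method": method, "failed": True,
                             "pi_hat": np.nan, "ci_low": np.nan,
                             "ci_high": np.nan, "pi_true": pi_true})
                continue
            rows.append({"rep": rep, "method": method, "failed": False,
                         "pi_hat": est.pi_hat, "ci_low": est.ci_low,
                         "ci_high": est.ci_high, "pi_true": pi_true})
    reps = pd.DataFrame(rows)
    summary = _summarize(reps, methods, n_reps)
    return SimulationResult(
        scenario_label=scenario_label or f"{scenario.population}-default",
        n_reps=n_reps,
        summary=summary,
        replicates=reps,
    )


def _summarize(reps: pd.DataFrame, methods, n_reps: int) -> pd.DataFrame:
    """Operating characteristics per method.

    Bias and RMSE are taken against each replicate's realized national
    proportion.  ``coverage`` is taken against the scenario's long-run
    national proportion (the Monte-Carlo mean of the realized truths): the
    variance estimators — sandwich, Rubin, bootstrap — quantify uncertainty
    for municipalities drawn afresh from the country-generating law, so
    that is the quantity their intervals are calibrated for.  Coverage of
    the same replicate's realized truth is reported as
    ``coverage_realized``; it runs structurally higher because the sampled
    counts appear in both the estimate and the realized truth.
    """
    pi_longrun = float(reps["pi_true"].mean()) if len(reps) else np.nan
    out = []
    for method in methods:
        sub = reps[(reps["method"] == method) & (~reps["failed"])]
        n_failed = int((reps["method"] == method).sum() - len(sub))
        err = sub["pi_hat"] - sub["pi_true"]
        mean_true = float(sub["pi_true"].mean()) if len(sub) else np.nan
        bias = float(err.mean()) if len(sub) else np.nan
        covered = (sub["ci_low"] <= pi_longrun) & (pi_longrun <= sub["ci_high"])
        covered_real = (sub["ci_low"] <= sub["pi_true"]) & (
            sub["pi_true"] <= sub["ci_high"]
        )
        out.append(
            {
                "method": method,
                "n_reps": n_reps,
                "n_failed": n_failed,
                "valid": n_failed <= 0.10 * n_reps,
                "mean_estimate": float(sub["pi_hat"].mean()) if len(sub) else np.nan,
                "mean_true": mean_true,
                "bias": bias,
                "relative_bias": bias / mean_true if len(sub) else np.nan,
                "rmse": float(np.sqrt((err**2).mean())) if len(sub) else np.nan,
                "empirical_se": float(sub["pi_hat"].std(ddof=1)) if len(sub) > 1 else np.nan,
                "coverage": float(covered.mean()) if len(sub) else np.nan,
                "coverage_realized": float(covered_real.mean()) if len(sub) else np.nan,
                "mean_ci_width": float((sub["ci_high"] - sub["ci_low"]).mean())
                if len(sub)
                else np.nan,
            }
        )
    return pd.DataFrame(out).set_index("method")


@dataclass
class RobustnessGrid:
    """The 2x2 misspecification grid, each cell a SimulationResult."""

    cells: dict[str, SimulationResult] = field(default_factory=dict)

    CELLS = (
        "both_correct",
        "sampling_wrong",
        "outcome_wrong",
        "both_wrong",
    )

    def to_frame(self) -> pd.DataFrame:
        frames = []
        for cell, res in self.cells.items():
            f = res.summary.reset_index()
            f.insert(0, "cell", cell)
            frames.append(f)
        return pd.concat(frames, ignore_index=True)


_CELL_SWITCHES = {
    "both_correct": (),
    "sampling_wrong": ("omit_covariate_in_sampling",),
    "outcome_wrong": ("omit_covariate_in_outcome",),
    "both_wrong": ("omit_covariate_in_sampling", "omit_covariate_in_outcome"),
}


def default_grid_scenario(population: str = "fsw") -> Scenario:
    """The scenario the robustness grid runs on: the DR-like default with the
    exact-logistic purposive stage, so the both-correct cell's sampling model
    is genuinely correctly specified."""
    return default_scenario(population, selection="logistic")


def double_robustness_suite(
    base: Scenario | None = None,
    n_reps: int = 500,
    seed: int = 0,
    M: int = 20,
    B: int = 200,
    methods: Sequence[str] = METHODS,
    cells: Sequence[str] = RobustnessGrid.CELLS,
) -> RobustnessGrid:
    """Run the 2x2 working-model misspecification grid.

    Every cell sees the same generative scenario; only the analysis-model
    specifications differ.  Cells reuse the same master seed so replicate
    countries are shared across cells, which removes between-cell Monte
    Carlo noise from the comparisons.
    """
    if base is None:
        base = default_grid_scenario()
    grid = RobustnessGrid()
    for cell in cells:
        grid.cells[cell] = run_scenario(
            base,
            methods=methods,
            n_reps=n_reps,
            seed=seed,
            M=M,
            B=B,
            misspecification=_CELL_SWITCHES[cell],
            scenario_label=cell,
        )
    return grid


_REPORT_COLUMNS = [
    "cell",
    "method",
    "n_reps",
    "n_failed",
    "valid",
    "mean_estimate",
    "mean_true",
    "bias",
    "relative_bias",
    "rmse",
    "empirical_se",
    "coverage",
    "coverage_realized",
    "mean_ci_width",
]


def render_report(results: SimulationResult | RobustnessGrid, path: str | Path) -> None:
    """Write the result grid as CSV plus a markdown summary table.

    ``path`` is the CSV destination; the markdown lands next to it with a
    ``.md`` suffix.  Re-rendering from the saved CSV reproduces the markdown
    byte for byte.
    """
    path = Path(path)
    if isinstance(results, RobustnessGrid):
        frame = results.to_frame()
    else:
        frame = results.summary.reset_index()
        frame.insert(0, "cell", results.scenario_label)
    frame = frame[_REPORT_COLUMNS]
    frame.to_csv(path, index=False)
    path.with_suffix(".md").write_text(_markdown_table(frame))


def render_report_from_csv(csv_path: str | Path, md_path: str | Path) -> None:
    frame = pd.read_csv(csv_path)
    Path(md_path).write_text(_markdown_table(frame[_REPORT_COLUMNS]))


def _markdown_table(frame: pd.DataFrame) -> str:
    show = frame.copy()
    for c in show.columns:
        if show[c].dtype.kind == "f":
            show[c] = show[c].map(lambda v: f"{v:.4g}" if pd.notna(v) else "")
    header = "| " + " | ".join(show.columns) + " |"
    sep = "| " + " | ".join(["---"] * len(show.columns)) + " |"
    body = [
        "| " + " | ".join(str(v) for v in row) + " |"
        for row in show.itertuples(index=False)
    ]
    return "\n".join([header, sep, *body]) + "\n"
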