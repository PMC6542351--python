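# Methods

This note records the statistical model, the estimators and their variance
estimators as implemented, the synthetic data-generating process used for
validation, and the numerical and design choices that were genuinely open.

## Estimand and assumptions

The unit is the municipality. For key population *p* and municipality *i*,
`Y_i` is the key population count, `N_i` the candidate population (women
15–49 for FSW; people assigned male sex at birth 15–49 for MSM/TGW), and the
estimand is the national proportion `pi = sum(Y) / sum(N)`. Direct
estimates `Y_i` exist only where the sampling indicator `S_i = 1`; the
contextual covariates `Z_i` are complete for all municipalities.

Identification rests on (a) *conditional exchangeability*: `Y` is
independent of `S` given `Z` — selection may depend on context but not,
beyond that, on the key population size itself; and (b) *positivity*: every
covariate stratum containing municipalities has nonzero sampling
probability. Neither is checkable from sampled data alone; the
`positivity_table` (default: population-density tertiles × poverty
tertiles) and `balance_table` diagnostics make violations visible, and the
`diagnose` CLI exits nonzero when a stratum has municipalities but no
sampled ones.

Direct estimates are treated as known quantities: no measurement error or
within-municipality sampling variance is propagated. Counts are accepted as
nonnegative reals (direct estimates are themselves estimates and need not
be integers); all model fits are quasi-likelihood-valid under non-integer
outcomes.

## Working models

Both working models use the same design: intercept, binary covariates as
linear terms, and each continuous covariate as a linear term plus a
restricted quadratic spline basis. With knots `t_1 < … < t_K`, basis column
`j` is `[(x − t_j)_+² − (x − t_K)_+²] / (t_K − t_1)` — zero below the first
knot, exactly linear above the last, continuously differentiable
everywhere. Default: 3 knots at the 5th/50th/95th percentiles of the
*full-country* distribution (so a model fit on sampled rows predicts
unsampled rows on the same basis); a covariate with fewer than 25 distinct
values falls back to its linear term, which protects rank with ~50 sampled
municipalities. The knot-span normalization keeps the columns on the scale
of `x` (better GLM conditioning); any full-rank linear reparameterization
gives identical fitted probabilities, so the choice is inferentially
neutral.

* Sampling model: maximum-likelihood logistic regression of `S` on the
  expanded design over all `k` municipalities. Perfect separation and rank
  deficiency raise errors naming the problem; there is deliberately no
  penalization fallback, which would silently change the estimand.
* Outcome model: Poisson regression of `Y` on the expanded design with
  offset `log N` over the sampled rows, optionally weighted.

Both are solved by a dedicated Newton/IRLS routine (deviance step-halving,
relative coefficient tolerance 1e-10, 100-iteration cap) because the
simulation study and the AIPW bootstrap refit these small models hundreds of
thousands of times; coefficients and sandwich variances are cross-checked
against statsmodels GLM in the test suite.

## Estimators

**Complete case.** Intercept-only Poisson with offset over sampled rows;
the MLE is exactly `sum_s Y / sum_s N`. CI from the robust sandwich on the
log scale (chosen for symmetry with IPSW; the underlying source does not
pin down a method for the crude estimator).

**IPSW.** The same estimating equation weighted by `W_i = 1 / Pr(S_i=1 |
Z_i)`, giving `sum_s WY / sum_s WN`. The variance treats the weights as
*estimated*: the logistic score equations are stacked with the weighted
rate equation and the influence function is
`[S_i W_i (Y_i − N_i pi) + C h_i] / A`, where `C` collects the derivative
of the weighted residual sum with respect to the sampling coefficients and
`h_i` is the logistic influence. The weights-as-known sandwich is also
implemented (used automatically when weights are supplied without a design
matrix) but is conservative: in the validation scenario its 95% intervals
covered ~99% of the time, against ~94% for the joint sandwich.

**Multiple imputation.** The unweighted outcome model on sampled rows gives
`(beta_hat, Sigma_hat)` (model-based covariance). For each of `M`
imputations, `beta^(m) ~ MVN(beta_hat, Sigma_hat)` (non-PSD covariance
repaired by eigenvalue clipping at zero) and each unsampled count is drawn
`Y_i^(m) ~ Poisson(N_i exp(Z_i beta^(m)))` — a proper-MI random draw, not
the expected count, so Rubin's between-imputation variance reflects both
coefficient and count uncertainty. Each completed dataset is analysed by
the intercept-only Poisson over all municipalities; pooling is on the log
scale: point = mean of `log pi^(m)`, total variance `T = W + (1 + 1/M) B`,
CI from the t distribution with `nu = (M−1)(1 + W/((1+1/M)B))²` (normal
when `B = 0`). The MI analysis model is deliberately unweighted —
imputation already performs the selection adjustment, and weighting on top
would double-correct.

**Augmented IPSW.** The regression form of the doubly robust estimator:
fit the sampling model, fit the IPSW-weighted outcome model on sampled
rows, predict `Yhat_i` for *every* municipality, and take
`pi_hat = sum(Yhat) / sum(N)`. Because the weighted score equations include
the intercept, `sum_s W Yhat = sum_s W Y`, which is what delivers
consistency when only the sampling model is correct; when only the outcome
model is correct the predictions themselves are consistent. SE = the
standard deviation of `log pi_hat` over `B` bootstrap resamples of the `k`
municipalities with replacement (each row keeps its `S`; resampling the
inferential units, not stratified by `S`). A resample whose models fail
(separation, lost sampling class, rank deficiency) or whose estimate falls
outside (1e-8, 1) — the signature of quasi-separation producing
astronomical weights — is discarded and logged; more than 10% discards is
an error. CI: `exp(log pi_hat ± 1.96 SE)`.

All four report the implied national count `pi_hat × sum(N)` with linearly
scaled interval endpoints; percentages appear only at the display layer.

## Covariate surfaces

Survey-cluster indicators (HIV prevalence, female education, adolescent
pregnancy) are interpolated by Delaunay triangulation with piecewise-linear
interpolation, evaluated at the centers of a regular grid (default 100×100
over the bounding box) and kept only inside the convex hull of the cluster
points; municipality values are the arithmetic mean over a municipality's
valued cells. Linear interpolation was chosen over spline or geostatistical
alternatives because it is deterministic, cannot overshoot the observed
range, and reproduces affine surfaces exactly — which the tests exploit as
an oracle. A municipality whose cells all fall outside the hull receives
the nearest valued cell's value, flagged as imputed, so downstream
covariates stay complete without hiding the extrapolation. Cell membership
uses centers, coordinates are planar; both are configurable-scale
simplifications appropriate for a country of small extent.

## Synthetic countries

`generate_country` draws a country of `k = 154` municipalities in 31
provinces. Log population density is Normal; poverty is Beta with mean
decreasing in density; HIV prevalence Beta with mean increasing in poverty;
tourism, border/port and university are Bernoulli with density-linked
probabilities; adolescent pregnancy and female education follow poverty.
Denominators are rounded lognormals increasing with density (national total
≈ 2.4 million). True rates are `pi_i = exp(beta' Z_i)` capped at 0.5 (a
scenario where the cap binds for >5% of municipalities is rejected as too
extreme), with an optional centered lognormal municipality-level dispersion
(`rate_dispersion_sd`, default 0 — the default surface is exactly
log-linear; positive values are a stress switch for the working models).
Counts are Poisson with mean `N_i pi_i` capped at `N_i` (Binomial switch
available).

Sampling is two-stage. The purposive stage scores municipalities on a
perceived-risk index (loading positively on density and tourism, negatively
on poverty) and either (`top_n`, the fixture default) takes the 30 highest
after adding Gumbel noise — noisy stakeholder prioritization, under which a
logistic sampling model is only approximately correct — or (`logistic`,
used by the simulation grid) draws independent Bernoulli selections from
the same index with the intercept calibrated to an expected 30; the second
mode makes the fitted sampling model genuinely correctly specified, which
is what "both models correct" must mean for the coverage experiments. The
random stage draws 20 municipalities uniformly from the remainder. Selection
uses covariates and independent noise only — never the counts — so
conditional exchangeability holds by construction while marginal
exchangeability fails.

Default effect sizes (rate decreasing in density, increasing in poverty;
selection favoring dense, less-poor, touristy areas) were calibrated once so
that the crude complete-case estimator understates the truth by roughly
20–30% — the qualitative failure mode that motivates the adjusted
estimators — and then frozen. Intercepts put the three populations near
3.7% (FSW-like), 1.2% (MSM-like) and 0.19% (TGW-like).

What the generator does *not* emulate: measurement error in the direct
estimates, within-municipality survey design, spatial correlation beyond
what the shared covariates induce, or temporal change between the two
sampling stages. Passing tests therefore validate the estimators under
their stated assumptions; they do not certify performance under
measurement error or unmeasured confounding of selection.

## Simulation study

`run_scenario` generates independent replicate countries from spawned
substreams of one master seed, applies each estimator, and summarizes bias,
relative bias, RMSE (against each replicate's realized national
proportion), empirical SE, mean CI width and coverage. Coverage is
measured against the scenario's long-run national proportion (the
Monte-Carlo mean of the realized truths): the sandwich, Rubin and bootstrap
variances all quantify uncertainty for municipalities drawn afresh from the
country-generating law, so that is the quantity their intervals are
calibrated for. Coverage of the same replicate's realized truth is also
reported (`coverage_realized`); it runs structurally higher — near 1 —
because the sampled counts appear in both the estimate and the realized
truth, and the purposively sampled municipalities carry a large share of
the national denominator.

The 2×2 double-robustness grid crosses {sampling model correct / wrong} ×
{outcome model correct / wrong} on identical replicate countries (only the
analysis-model specifications differ, which removes between-cell Monte
Carlo noise). A "wrong" model omits the contextual covariates entirely —
the crude intercept-only specification, i.e. the naive
apply-the-average-everywhere approach the adjusted estimators exist to
replace. Partial omission was tried first but the retained covariates
proxy the omitted ones and dilute the designed failure below a decisive
level.

Defaults are sized for a desktop run: 500 replicates with `M = 20`
imputations and `B = 200` bootstrap replicates inside simulations (the
`estimate` CLI defaults are `M = 50`, `B = 1000` for one-shot analyses);
the full grid completes in roughly ten minutes on one core. Failed
replicates are counted and excluded, never averaged over; a method with
more than 10% failures in a cell is flagged invalid.

## Known limitations

* Uncertainty in the direct estimates themselves is not propagated; CIs are
  accordingly narrow (a hierarchical extension would widen them).
* Municipality-level estimates are out of scope — only the national
  aggregate is identified under the stated assumptions.
* The AIPW bootstrap SE is a percentile-free normal-theory interval on the
  log scale; heavy-tailed bootstrap distributions are handled by the
  degenerate-replicate guard rather than by studentization.
* With ~50 sampled municipalities, rich covariate specifications can
  exhaust the outcome model's degrees of freedom; the spline fallback and
  the loud rank/separation errors are guardrails, not cures.
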