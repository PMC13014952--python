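# Methods

This note records the statistical procedure the package implements, the
defaults and why they were chosen, the numerical details that matter for
reproducing results, and what the synthetic-data experiments do and do not
establish about real data.

## Outcome construction

The outcome is the monthly count of firearm-violence *incidents* — events in
which at least one person was injured or killed by gunfire — per 1,000,000
residents of a state. Victim counts are kept only to classify incidents;
an event with five victims is one incident. Records without any casualty
(warning shots, gun-involved robberies with no one hit) are filtered out
before aggregation, and the filter is idempotent.

Classification by intent: every injurious incident counts toward
`all_violence`. Assaults split into `homicide` (any death) and
`nonfatal_assault`; self-harm into `suicide` and `nonfatal_self_harm`; the
composites `other_directed` (assault + homicide) and `self_directed`
(self-harm + suicide) are implied by membership. An incident with both a
death and a nonfatal injury of the same intent counts once, in the fatal
category — *fatal dominance* — so the composite strata are exact sums of
their members. Unintentional and undetermined incidents contribute to
`all_violence` only. Unknown intent labels either raise (strict, default) or
map to `undetermined`.

Population denominators are annual and held constant within each calendar
year; no sub-annual interpolation is attempted. The default panel window is
2014-01 through 2021-12. The end is pinned there because incident
compilations changed how self-directed violence is captured from 2022
onward; extending the window is possible but warns. Law-enforcement-involved
and self-defense incidents are retained (they can be excluded via the
incident table before aggregation if a sensitivity analysis needs it).

## Treated cohort and donors

A state enters the treated cohort if

1. its ERPO effective date is on or after 2015-01-01 (enough pre-period),
2. on or before 2019-01-01 (enough post-period) — both bounds inclusive, and
3. monthly petition filings rose significantly after enactment.

The petition test is a one-sample t-test of post-enactment monthly counts
against zero, one-sided for an increase at alpha = 0.05 (a two-sided option
exists). Testing against zero is not a convenience: before an ERPO statute
exists the petition count is structurally zero, so the pre-period needs no
data. Fewer than two post months yields an inconclusive, non-passing result;
all-equal positive counts are an exact increase, reported at the smallest
positive float. The t statistic is invariant to rescaling all counts, so the
test does not depend on how petition volumes are normalized.

Donors are states with no ERPO effective date inside the panel window and no
missing covariate years. A state whose ERPO predates the window (e.g. a
2005 statute) is untreated *during the study period* and may donate if its
covariates are complete. The packaged policy catalog carries Colorado with a
nominal in-window effective date: its exclusion runs through the petition
test (its uptake, not its statute timing, is what disqualifies it), which is
how the cohort diagram for this design is usually drawn.

## Synthetic control

`SyntheticControl` solves the simplex-constrained weighted least squares
problem min over W of `(X1 − X0·W)' diag(V) (X1 − X0·W)` with `W ≥ 0`,
`ΣW = 1`.

**Predictors.** Covariates observed at state-year resolution are repeated
across that year's months, aggregated over the pre-period (mean, last, or
specific months), and combined with outcome-lag predictors — by default the
means of the first, middle and last thirds of the pre-period outcome series.
Every predictor row is z-scored across treated + donors before `V` is
applied, so no covariate dominates through its units; zero-variance rows are
dropped with a warning.

**Inner solve.** A non-negative least squares pass with a sum-to-one penalty
row proposes the active donor set; an exact KKT active-set refinement then
polishes to the constrained optimum. The solve is deterministic, satisfies
the simplex constraints within 1e-8 under any input, and on small instances
matches an exhaustive simplex grid search at step 0.005 within 1e-4
objective (verified over random instances with up to 4 donors and 3
predictors). An SLSQP backend is kept as an independent cross-check.

**Degeneracy tie-break.** With fewer predictors than donors the
predictor-matching problem can be exactly solvable by many weight vectors
(for example when one donor duplicates the treated unit and others can also
combine to match three predictor means). When the predictor objective is at
machine zero, the solve is repeated with the pre-period outcome series
appended below a heavily weighted copy of the predictors: among exact
predictor matches, the weights with the best pre-period outcome fit win.
The refinement never fires on non-degenerate problems and never worsens the
predictor objective.

**Importance V.** `v_mode="nested"` (default for single-state analyses)
minimizes the pre-period outcome MSPE of the inner solve over the predictor
simplex. The objective is only piecewise smooth (the inner active set
changes with V), so the search scatters candidates first — the uniform
vector, the simplex vertices, and seeded Dirichlet draws — then polishes the
best with SLSQP followed by Nelder–Mead. Identical inputs and seed give
bit-identical `W` and `V`. `v_mode="equal"` uses uniform importances; it is
the configuration used in the large simulation experiments below, where
thousands of fits are needed and the outcome-lag predictors already carry
the matching information. Nested fits are never worse than equal-V fits in
pre-period MSPE, by construction (the equal vector is among the candidates).

**Treatment-month convention.** The calendar month containing the effective
date is the first *post* month (a law effective 2016-12-08 makes 2016-12
post). Pre-period RMSPE is computed over months strictly before it.

## Inference

**Placebos.** Every donor is refit as pseudo-treated with the same treatment
month and predictor spec against the remaining donors; the actual treated
state never enters a placebo's donor pool. Individual placebo failures are
quarantined and recorded; the ensemble proceeds. An optional filter drops
placebos whose pre-period RMSPE exceeds a multiple of the treated unit's;
it is off by default because the ratio statistic already normalizes by
pre-period fit.

**Ranking p-value.** Units are ranked by the post/pre RMSPE ratio, one-sided
on the ratio (a ratio far above one means post-period divergence an
untreated unit should not show; gaps are signed, ratios are not). The
treated rank counts ties as at least as extreme, and p = rank / n with the
treated unit included in the denominator — at the study's geometry of 25
donors the smallest attainable p is 1/26 ≈ 0.04. The p-value is always an
integer multiple of 1/n.

**Fit gate.** A fit is uninterpretable when pre-period RMSPE exceeds 10% of
the treated unit's mean pre-period rate (`tau_relative = 0.10`), or exceeds
twice the median placebo pre-period RMSPE (`tau_placebo = 2.0`). The first
check catches absolute misfit, the second misfit relative to what the donor
pool supports; a zero mean pre-period rate disables the first. The
thresholds are tunable and every gate decision reports which check failed.
Note that under Poisson observation a small state's *own* sampling noise
bounds its attainable pre-period RMSPE from below, so the 10% default is
demanding for low-population units — intended behavior: their estimates are
genuinely hard to interpret.

**Yearly effects.** Post-period months are grouped into consecutive
12-month implementation years from the treatment month. The effect for a
year is the *sum* of its monthly gaps — incidents per 1M residents per year,
negative meaning a reduction — and the percent change divides by the
synthetic (counterfactual) annual rate. Two interval constructions are
offered and labeled in every export: the default normal interval from
within-year monthly variation, effect ± 1.96·√n·sd(monthly gaps), and a
placebo-quantile interval from the 2.5/97.5 percentiles of the placebos'
matching yearly sums. Neither is a claim about the construction used in any
particular prior analysis; both are stated heuristics. A truncated final
year is reported with the number of months it covers, and the yearly effects
sum to the total post-period gap.

## Study orchestration

One config drives: cohort selection → per-state synthetic control on the
overall outcome → fit gate → placebo inference → independent re-analysis per
intent stratum. Each treated state gets its own treatment month and its own
placebo ensemble, and every stratum is a full re-run on that stratum's panel
(the other-directed estimate comes from the combined assault+homicide panel,
not from summing two separate estimates). Excluded states carry no fits;
uninterpretable states carry no effect estimates. Statuses
excluded/uninterpretable/estimated partition the treated candidates. The
whole run is deterministic given the config and seed, and exports are
idempotent.

## Synthetic-data generator

The generator draws latent monthly rates from a linear factor model — the
data-generating process under which a convex donor combination is a valid
counterfactual:

    lambda_it = max(0, [delta_t + f_t' mu_i + eps_it] * covid_t + effect_it)

- `delta_t`: baseline 60 incidents per 1M per year (5/month — consistent
  with an annual state rate of roughly 60 per 1M implied by per-1M yearly
  effect sizes of a few incidents being single-digit percent changes), with
  a ±10% linear drift and 5% seasonality.
- `f_t`: standardized AR(1) factors (phi = 0.95, two by default) with unit
  loadings `mu_i` uniform on [0,1] for donors; the factor contribution is
  scaled to 30% of baseline. Treated loadings are convex combinations of
  donor loadings (`overlap=True`, a good synthetic control exists) or pushed
  outside the donor hull (`overlap=False`, to exercise the fit gate).
- `eps_it`: Gaussian rate jitter, sd 0.2 per 1M per month.
- `covid_t`: +20% multiplicative shock from 2020-03.
- `effect_it`: expressed as a fraction of the baseline monthly rate, so a
  −10% step injects a true yearly effect of exactly −0.10 × 12 × 5 = −6 per
  1M per year, recorded in the ground truth. Ramps grow linearly by
  implementation year.

Counts are Poisson at `lambda_it × pop_i / 1e6` with populations drawn
log-normally around 4M residents (so small states are realistically
volatile); `observation="exact"` returns expected counts for noiseless
recovery experiments. Default geometry mirrors the study: 10 treated, 25
donors, 96 months, effective dates spread over 2016–2019. Covariates are
noisy linear functions of the factor loadings (genuinely informative
predictors); petitions are zero before each treated state's effective date
and Poisson(5)/month after, with an optional year-on-year growth factor.
Incident records disaggregate each cell's count with iid intent draws
(assault 0.85, self-harm 0.05, unintentional 0.10 — media-sourced
compilations over-represent interpersonal violence) and intent-specific
fatality probabilities (0.25 / 0.90 / 0.05); aggregation reproduces the
panel cell for cell. Identical config and seed give byte-identical CSVs.

**What the generator does not emulate:** county-level heterogeneity and
within-state enforcement variation, cross-state firearm movement, media
reporting bias that censors nonfatal incidents, migration between states,
and covariates that confound rather than merely predict. Passing recovery
and calibration tests therefore establishes that the *pipeline* is correct
and calibrated under the factor model, not that real-data estimates are
unbiased under violations of it.

## Validation experiment sizes and observed behavior

The packaged experiments use: 500 null panels of 26 exchangeable units × 96
months for type-I calibration at the 5/26 level; 200 replicates for step
recovery and 100 for ramp monotonicity; 100 random small instances for the
grid-search certificate; equal-V fits with outcome-third predictors
throughout (one fit at this size takes a few milliseconds, a 26-unit
ensemble well under a tenth of a second).

Two honest caveats from these experiments. First, the treated unit's donor
pool has one more member than each placebo's (the treated unit never donates
to placebos), which gives the treated unit a slightly better expected
pre-period fit and hence a mild over-rejection — about 0.21 observed against
a nominal 5/26 ≈ 0.19 when pooling thousands of null panels. Second, under
heavy-tailed populations a very small treated state's RMSPE ratio is noise-
dominated, so even a large true effect need not reach rank 1; the
p-value-geometry demonstration therefore draws states at comparable
populations (`pop_log_sd=0.3`), which is also the regime of the mid-size
states whose smallest-attainable p-value the demonstration illustrates.

## Known limitations

- The rank p-value's resolution is 1/(J+1); with few donors it cannot be
  small, and the test has no power against effects that do not move the
  RMSPE ratio.
- The gate thresholds are conventions, not estimates; results should be
  reported with the gate decision and its reasons, as the exports do.
- The yearly-effect intervals are heuristics (monthly-variation normal or
  placebo quantiles), not exact permutation intervals.
- Nested V optimization is a global search over a piecewise-smooth
  objective; it is reproducible by seed and never worse than equal V, but
  global optimality is not certified for large predictor counts.
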