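# Methods

## Data-generating mechanism

A trial replication draws, in a fixed order (baselines, random effects, arm
allocation, winter flags, daily matrix row-major, from one `numpy` PCG64
stream), the following quantities:

* **Baseline MVPA** baseline_i ~ log-normal with natural-scale mean 77 and SD
  52 min/day — the average daily MVPA over a one-month pre-randomisation
  period. Daily activity is right-skewed, hence the log-normal.
* **Participant random effect** α_i ~ N(0, σ² = 4 (min/day)²), entering the
  *natural-scale* mean additively alongside baseline.
* **Arm allocation**: exactly `round(n·r_t/(r_t+r_c))` of the n participants
  are treated (29:15 for 44 at 2:1; 22:22 at 1:1), in uniformly random order.
  Rounding is half-away-from-zero throughout, so exact counts are
  deterministic functions of the scenario parameters.
* **Winter recruitment**: exactly `round(n·prop_winter)` participants are
  flagged, independently of arm. Season is a binary label, not a calendar.
* **Daily outcome** y_ij ~ log-normal with natural mean μ_ij (the additive
  linear predictor of treatment, season, week-1 observer effects, their
  treatment interactions, and α_i) and natural SD 46 min/day. Days are
  conditionally independent given α_i; the only within-participant
  correlation is that induced by baseline_i and α_i.

Both log-normals are parameterised by *moment matching*: given natural-scale
(mean m, SD s), the log-scale parameters are σ² = ln(1 + (s/m)²),
μ = ln m − σ²/2. The stated means and SDs are interpreted as natural-scale
moments because the effect sizes (e.g. the treatment effect of 12.5 min/day)
are additive on the minutes scale.

Numerical guard: μ_ij is floored at `mean_floor` = 1 min/day before moment
matching, since a tiny baseline draw combined with a negative α_i can push
the linear predictor to ≤ 0, where the log-normal is undefined. Occurrences
are counted in the dataset's metadata; under the default parameters they are
rare (none observed in typical replications).

"Week 1" is follow-up days 1–7 inclusive, 1-indexed.

## Missingness and compliance

Missingness operates at the day level: a missing day stands for a day that
failed the wear-time compliance rule of the motivating device (≥ 600 minutes
of wear while awake). Wear time itself is not simulated; the 600-minute
threshold is carried in `ComplianceRule` as documentation of what a missing
day means.

* **MCAR**: an exact `round(prop_participants·n)` participants are selected
  uniformly; each loses an exact `round(prop_days·period)` uniformly chosen
  days within the measurement period. Selection never depends on the
  outcome, so the observed-day mean is unchanged in expectation.
* **MNAR**: the same exact counts, but each affected participant loses their
  *lowest-activity* days (ties broken toward the earliest day, via a stable
  sort). This emulates the device being left off on sedentary days, and
  weakly raises every affected participant's observed mean — the source of
  the upward bias in the treatment-effect estimate, because the size of the
  truncation uplift depends on the participant's activity level and hence
  (through the log-normal's shape) differs between arms.

A participant is analysed only if their observed-day count within the
measurement period reaches the inclusive threshold: 14 days for the 28-day
period, and `ceil(period/2)` in general (7 for the 14-day period, where the
rule is only stated for the month-long period and the scaling is this
package's choice). With `prop_days = 0.5` affected participants sit exactly
at the boundary and are retained. Excluded participants are dropped
(complete-case analysis) and counted.

## Primary analysis

The per-participant summary is the *mean* over observed days in the
measurement period. (Written as a bare indicator-weighted sum, the summary
would conflate the amount of missingness with the outcome level; the mean is
the quantity the compliance rule is designed to stabilise.) The ANCOVA
ȳ = β₀ + β₁·baseline + β₂·treat + ε is fitted by ordinary least squares with
the unbiased residual-variance estimator s² = RSS/(n−3) and classic
standard errors. The fit is a direct normal-equations solve in `numpy`
rather than a statsmodels call because it executes 10,000+ times per
scenario cell; the test suite verifies agreement with both an independent
normal-equations oracle and `statsmodels.OLS` to high precision. Baseline
stratification factors of the motivating trial are deliberately omitted.

## Monte Carlo evaluation

Each scenario cell runs `nsim` (default 10,000) replications. Replication
*r* of a cell is seeded by the 31-bit SHA-256 hash of `(base_seed,
cell_label, r)`, so cells are mutually independent, results are
order-independent, and any replication can be reproduced in isolation. The
performance measures are the mean of β̂₂ and the mean of SE(β̂₂), each
reported with its Monte Carlo error (sample SD of the draws / √nsim; the
same formula is applied to the SE draws, the standard choice). Figure-style
plots draw error bars at 1.96 × Monte Carlo error. Replications whose fit
fails (e.g. no participant passes compliance) are counted and excluded; a
cell aborts if more than 1% fail — under the default grids none do.

The built-in grids use 5 evenly spaced effect sizes {0, 2.5, 5, 7.5, 10}
min/day for the seasonal and observer effects (the stated range is 0–10
without explicit spacing), winter/missing-participant proportions
{0.1, 0.2, 0.5}, missing-day proportions {0.05, …, 0.5} in steps of 0.05
plus a complete-data reference cell, and the interaction convention
δ₃ = 0.1·δ₂, δ₅ = 0.1·δ₄ when "with interaction" is requested. Grid spacing
is configurable.

## Validation metrics

* **Test-retest reliability**: one-way random-effects, single-measurement
  ICC(1,1) between two per-subject summaries (e.g. split halves of the
  wearing period), computed from the one-way ANOVA mean squares:
  ICC = (MSB − MSW)/(MSB + (k−1)·MSW), k = 2. The one-way model is the
  appropriate form for split-period summaries, where no rater structure
  exists; the result records the model used.
* **Stability curve**: for each candidate measurement-period length L, each
  subject's summary is recomputed over bootstrap resamples of L days and the
  subject-level coefficient of variation (%) of those replicate summaries is
  averaged across subjects. CV is used because the robustness statistic is
  conventionally reported as a percentage of the summary's level; for an iid
  signal summarised by the mean it decays like 1/√L.
* **Convergent validity**: Pearson or Spearman correlation (scipy) between
  the digital summary and a traditional outcome.
* **Known-groups validity**: group medians and their difference between a
  disease cohort and controls; no hypothesis test is attached by default.

## What the synthetic data do and do not emulate

The generator reproduces the *moments and effect structure* a day-level
wearable endpoint plausibly exhibits: right-skewed daily values, stable
between-participant heterogeneity, additive season/observer shifts, and
informative missingness toward low-activity days. It does not model
within-day (epoch-level) signal, day-to-day autocorrelation beyond the
shared random effect, calendar-driven recruitment, participant dropout over
time, or device-specific artefacts. Passing tests therefore demonstrate the
behaviour of the *estimator under the stated mechanism* — e.g. that MNAR
missingness biases the ANCOVA upward — not that real actigraphy data meet
these assumptions.

## Problem sizes and numerical choices

The acceptance script and the end-to-end tests use 10,000 replications per
cell for the 2:1 design, matching the reported precision (Monte Carlo error
≈ 0.03 min/day for the mean estimate); the 1:1 supplementary variant is
checked at 2,000 replications, whose proportionally wider 3× Monte Carlo
error tolerances the directional effects still clear by a comfortable
margin. Unit-level Monte Carlo checks (moment-matching at 10⁶ draws,
null-ICC at n = 5,000) use fixed seeds. Degenerate inputs are rejected
explicitly: single-arm analysis sets, rank-deficient design matrices,
zero-variance ICC/correlation inputs, empty analysable sets.

## Known limitations

* Complete-case analysis is the only estimator; no imputation or mixed
  models are provided.
* MAR mechanisms between MCAR and MNAR are not implemented.
* The compliance threshold for periods other than 28 days is an
  extrapolation (`ceil(period/2)`), and the default grids never combine
  missingness with the 14-day period.
* Monte Carlo cells execute serially; grids are embarrassingly parallel but
  no scheduler is built in.
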