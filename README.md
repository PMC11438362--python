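# actitrial

A simulation framework for clinical trials whose primary endpoint is a
wearable-derived daily activity measure (minutes of moderate-to-vigorous
physical activity, MVPA). It is aimed at trial statisticians and
methodologists who need to quantify, before a trial runs, how seasonal
variation, observer (Hawthorne) effects, the length of the measurement
period, and missing wear days propagate into the bias and standard error of
the primary treatment-effect estimate. A small companion library provides
the validation statistics used when qualifying a digital endpoint
(test-retest ICC, stability vs measurement-period length, convergent and
known-groups validity).

## The model

Each simulated trial has *n* = 44 participants randomised 2:1 (optionally
1:1) to treatment or control, followed for 28 days. The daily outcome
y<sub>ij</sub> (min/day MVPA) for participant *i* on day *j* is log-normal on
the natural scale with SD 46 and mean

μ<sub>ij</sub> = baseline<sub>i</sub>
 + δ₁·I(treat<sub>i</sub>)
 + δ₂·I(winter<sub>i</sub>) + δ₃·I(winter<sub>i</sub>)·I(treat<sub>i</sub>)
 + δ₄·I(j ≤ 7) + δ₅·I(j ≤ 7)·I(treat<sub>i</sub>)
 + α<sub>i</sub>

where baseline<sub>i</sub> ~ log-normal(mean 77, SD 52), α<sub>i</sub> ~
N(0, 4), δ₁ = 12.5 min/day is the treatment effect, δ₂/δ₃ model a seasonal
effect for winter-recruited participants and its treatment interaction, and
δ₄/δ₅ model a first-week observer effect and its interaction. Days are
missing completely at random (MCAR) or not at random (MNAR: the
lowest-activity days are lost), and a participant enters the analysis only
with ≥ 14 observed days in the 28-day measurement period.

The estimand is β₂ (and its standard error) in the baseline-adjusted ANCOVA
fitted to per-participant means over compliant days:

ȳ<sub>i·</sub> = β₀ + β₁·baseline<sub>i</sub> + β₂·treat<sub>i</sub> + ε<sub>i</sub>

Performance of each scenario is summarised across Monte Carlo replications
by the mean of β̂₂ and the mean of its SE, each with a Monte Carlo error
(sample SD / √nsim).

## Worked example

```python
import actitrial as at

# one simulated trial under the default design, analysed end to end
ds = at.simulate_trial(at.DesignConfig(), at.EffectScenario(), seed=1)
res = at.analyse_trial(ds)
print(f"single trial: beta2 = {res.beta2:.2f} (SE {res.se_beta2:.2f}), "
      f"n_analysed = {res.n_analysed}")

# a Monte Carlo cell: MNAR missingness on half the cohort, half the days
cell = at.ScenarioCell(
    missingness=at.MissingnessSpec("MNAR", prop_participants=0.5, prop_days=0.5),
    nsim=2000, base_seed=1)
s = at.run_cell(cell)
print(f"MNAR cell: mean beta2 = {s.mean_beta2:.3f} "
      f"(MC error {s.mc_error_mean:.3f}), mean SE = {s.mean_se:.3f}")
```

prints

```
single trial: beta2 = 11.41 (SE 3.39), n_analysed = 44
MNAR cell: mean beta2 = 13.355 (MC error 0.139), mean SE = 6.274
```

The single replication estimates the true effect of 12.5 min/day with the
sampling noise of a 44-participant trial. The MNAR cell shows the two
consequences of informative missingness: the mean estimate is biased upward
(13.36 vs the true 12.5, far beyond the Monte Carlo error of 0.14) and the
mean standard error roughly doubles relative to the complete-data value of
about 2.85.

The full study grids (seasonality × winter proportion, observer effect ×
measurement period, missingness mechanism × proportions, under both
allocation ratios) run from the command line:

```sh
actitrial replicate-paper --nsim 10000 --seed 1 --out-dir results
actitrial run my_config.yaml        # custom grids from a YAML config
actitrial simulate --seed 1 --out trial.csv
actitrial validate --seed 1         # validation-metrics demo
```

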