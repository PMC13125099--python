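# survext

Life-table-referenced survival extrapolation and lifetime healthcare cost
estimation for registry-style cohorts, on a monthly grid.

## The problem

Registry follow-up of a diagnosed cohort is always truncated — a cancer
registry may observe 10–19 years of survival for patients whose remaining
lifetimes span decades. Five- or ten-year survival rates are hard to compare
across cohorts with different age and sex mixes, and they say nothing about
how many years of life a diagnosis actually costs. `survext` implements the
semiparametric extrapolation approach used in health-economics studies of
national insurance data: it extends the observed Kaplan–Meier curve to
lifetime by borrowing the mortality of age-, sex-, and calendar-year-matched
referents simulated from national life tables, and reports

- **life expectancy (LE)** after diagnosis: the area under the completed
  survival curve, in years;
- **loss of LE** (expected years of life lost): matched-referent LE minus
  cohort LE;
- **lifetime healthcare cost** and **cost per life-year**: the mean monthly
  cost function (with its end-of-life surge) integrated against survival,
  extrapolated months discounted at 3%/year;
- **cumulative incidence rates** CIR₍₂₀–₇₉₎ = 1 − exp(−Σᵢ IRᵢ·Δtᵢ) from
  age- and sex-specific incidence rates.

## The method

Let S₁(t) be the cohort's Kaplan–Meier survival at month t and S₀(t) the
pooled survival of Monte Carlo referents drawn from the life table (each
index patient contributes `n_referents_per_patient` referents, followed to
death). The survival ratio W(t) = S₁(t)/S₀(t) is clipped into (ε, 1−ε̂),
logit-transformed, and fitted with a restricted (natural) cubic spline of
the month index — linear beyond its boundary knots — by inverse-variance
weighted least squares. The fit predicts logit W one month ahead;
Ŝ₁(t+1) = expit(logit Ŵ)·S₀(t+1) becomes the next "observed" point, the
earliest window month is dropped, and the spline is refitted — a rolling
one-month-ahead extrapolation that stops when Ŝ₁ < 0.01. Standard errors
come from a patient-level nonparametric bootstrap with the referent curve
held fixed.

The upper clip 1−ε̂ is a sampling-noise floor, ε̂ = max(0.005, SE(Ŵ(T))):
ratios statistically indistinguishable from 1 are treated as 1-within-noise,
which keeps the logit (singular at W = 1) from turning pure noise into a
spurious trend. See `docs/methods.md` for the full account.

Every input can be simulated by the `synthetic` module with known ground
truth: a Gompertz life table, cohorts with a prescribed excess hazard (so
true LE follows from brute-force summation of the discrete hazards), monthly
costs with a lognormal baseline and terminal surge, and Poisson incidence
scenarios.

## Worked example

```python
from survext import (ScenarioConfig, make_life_table, make_cohort,
                     referent_survival_curve, km_estimate, rolling_extrapolate)

cfg = ScenarioConfig(n_patients=2000, excess_delta=0.01, seed=1)
table = make_life_table(cfg)
cohort, truth = make_cohort(cfg, table)       # 120-month truncated follow-up
ref = referent_survival_curve(cohort, table, n_per_patient=100, rng=1001)
res = rolling_extrapolate(km_estimate(cohort), ref)
t = truth["overall"]
print(f"LE after diagnosis : {res.LE_index:.2f} years   (generator truth {t['true_le_index_years']:.2f})")
print(f"Matched-referent LE: {res.LE_ref:.2f} years")
print(f"Loss of LE         : {res.loss_LE:.2f} years   (generator truth {t['true_loss_le_years']:.2f})")
```

prints

```
LE after diagnosis : 6.01 years   (generator truth 6.31)
Matched-referent LE: 17.49 years
Loss of LE         : 11.48 years   (generator truth 11.22)
```

i.e. from only 10 years of observed follow-up the rolling extrapolation
recovers a ~6.3-year true LE within 5% and an 11.2-year true loss of LE
within 0.3 years, for a cohort carrying a constant 0.01/month excess hazard
over its matched referents.

The same analysis is available from the shell: `survext simulate` writes a
full synthetic scenario (life table, cohort, costs, CPI, incidence, truth
report), and `survext le / cir / costs / report` run the stratified analyses
and merge the summary tables.

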