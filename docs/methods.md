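# Methods

## Survival model and grid conventions

All computations live on a monthly grid: month index m is the interval
[m, m+1) after diagnosis, and S(m) is the probability of being alive at the
start of month m. A patient record with `followup_months = f, died = 1` died
during month index f−1 and enters the Kaplan–Meier estimator as a death at
time f; censored records were observed alive through month f−1. Within a
month, deaths are processed before censorings (the standard product-limit
tie rule, which makes small worked examples exactly reproducible). This
convention keeps S(0) = 1 identically, and makes "the months a patient is a
surviving case" exactly months 0..f−1 — the denominator used by the cost
module, so that mean cost × survivor count sums back to the raw spend
without correction terms.

Life expectancy is the trapezoidal area under S on the monthly grid divided
by 12. The trapezoid was chosen over a step-function sum as the
least-surprising deterministic rule; for an empirical survivor curve it
equals mean lifetime plus half a month, and it is what the brute-force truth
in the synthetic module uses as well, so estimator and oracle share one
integration convention.

## Matched referents

Referents matched on age, sex, and calendar year are simulated from the
life table year by year: at attained age a in calendar year y, death occurs
with the annual probability q(sex, y, a); the death month within the year is
uniform (the standard uniform-distribution-of-deaths assumption — the table
gives no sub-annual information). Years and ages beyond table coverage clamp
to the nearest covered entry, and q at the highest covered age is treated as
1 (closed table), so every simulated lifetime terminates. The pooled curve
of `n_referents_per_patient` referents per index patient (default 100,
chosen so that referent Monte Carlo noise is an order of magnitude below
index-cohort noise) is the reference survival S₀, followed to zero.

## Rolling spline extrapolation

The extrapoland is the logit of the survival ratio W(t) = S₁(t)/S₀(t) over
the observed months (month 0, where both curves are 1 by construction, is
dropped). Each step fits a restricted cubic spline of the month index —
natural boundary conditions, i.e. linear beyond the outer knots — predicts
logit W one month ahead, converts back through Ŝ₁ = expit(logit Ŵ)·S₀, and
rolls the fixed-length window forward by dropping its earliest month and
appending the prediction. Iteration stops when Ŝ₁ falls below
`stop_threshold` (default 0.01) or after `hard_cap_months` (default 1,200;
exceeding it sets `converged = False`). The extrapolated curve is forced to
be non-increasing (each predicted survival is capped by its predecessor),
and predicted logit ratios are clipped into the same bounds as observed
ones. Loss of LE is referent LE minus index LE by construction, so the
accounting identity loss + LE₁ = LE₀ holds to machine precision.

Three numerical choices here deserve explanation, because the naive
algorithm is unstable in exactly the regimes a validation study probes:

- **Noise-floor clipping.** The logit is singular at W = 1. In a cohort
  whose mortality is close to the referent law, Ŵ(t) fluctuates around 1,
  and mapping every ratio ≥ 1 to 1−10⁻⁶ produces logit values ≈ 13.8 while
  the genuinely-below-1 months sit around 5–8: the spline reads this as a
  steep decline and collapses the extrapolated curve. W is therefore capped
  at a constant 1 − max(ε_upper, z·SE(Ŵ(T))), with the delta-method SE from
  the Greenwood variances of both curves evaluated at the end of follow-up
  (defaults ε_upper = 0.005, z = 1): a ratio within one standard error of 1
  is treated as 1-within-noise. The floor is deliberately constant over the
  window — a time-varying cap would itself decline with t and inject a
  trend. The lower clip stays at ε = 10⁻⁶. For cohorts with real excess
  mortality the ratio leaves the floor within a couple of months and the cap
  is irrelevant.
- **Inverse-variance weighting.** Var(logit Ŵ(t)) ≈ (G₁(t)+G₀(t))/(1−W(t))²
  by the delta method, where G are cumulative Greenwood sums. Unweighted
  least squares lets the early months — which carry enormous logit variance
  and, in a diseased cohort, a steep curvature irrelevant to the tail —
  leak into the fitted boundary slope. The spline is therefore fitted by
  weighted least squares with w(t) = (1−W)²/(G₁+G₀). Appended predicted
  points inherit the last observed month's weight. When a curve carries no
  at-risk information the fit falls back to unweighted. `fit_rcs` itself
  defaults to plain least squares; the weighting is a property of the
  rolling algorithm.
- **Knots.** Six knots at the (5, 23, 41, 59, 77, 95)th percentiles of the
  window months. On noise-free exact curves, four knots leave the boundary
  slope ~70% steeper than the true local slope of logit W (misfit leakage),
  biasing LE by −6 to −10% in the validation scenarios; seven knots are
  nearly unbiased there but let the boundary flex on noise, with errors an
  order of magnitude larger on noisy cohorts. Six knots were selected from
  that grid as the best bias/stability compromise and left configurable
  (`n_knots`). Because the natural spline is linear beyond its boundary
  knots, the long-run extrapolation is effectively a linear continuation of
  logit W at the estimated terminal slope; with the true ratio following a
  constant excess hazard, that linearization alone contributes about −1.5%
  LE bias at δ = 0.01/month from 120 months of follow-up — an inherent
  property of the method, not of the implementation.

Extrapolation requires at least 24 observed months and errors out, with a
diagnostic, if the reference curve reaches zero while index survival is
still above the stop threshold (remedy: more referents or a deeper life
table).

## Uncertainty

SEMs of LE and loss of LE come from a nonparametric bootstrap over patients
(default 100 replicates), re-running the Kaplan–Meier fit and the rolling
extrapolation per replicate with the referent curve held fixed. Holding the
referent fixed makes the loss-of-LE SEM equal the LE SEM by construction;
both are reported. Replicates that fail to converge are dropped and counted;
more than 20% failures aborts. The resampling scheme is this package's
declared choice — jackknife or referent-resampling variants would be equally
defensible.

## Lifetime costs

Observed months: mean cost per surviving case, c(m) = (total spend of
patients alive in month m)/(number alive in month m); patients with no claim
contribute zero to the numerator and one to the denominator. Costs are first
deflated to base-year (2017) prices with a CPI index and converted to USD at
30.44 TWD/USD.

End of life: decedents' months are aligned backwards from death and a
single change-point scan over window lengths L = 1..12 picks the L
maximizing |mean terminal cost − mean stable cost| (smallest L on ties; the
scan is exhaustively testable against brute force). For an extrapolated
month t, the probability that a patient alive at t dies within the next k
months is read off the extrapolated curve, and the mean cost is the
correspondingly weighted average of the terminal profile and the stable
mean — so the cost function rises endogenously as the cohort approaches
death.

Lifetime cost is Σₜ c(t)·S(t)·d(t) with d(t) = 1 over observed months and
(1.03)^(−(t−t₀)/12) from the first extrapolated month t₀ (discounting
anchored at the extrapolation boundary; anchoring at diagnosis is available
via `discount_all`). Cost per life-year is reported in two labelled
variants — lifetime cost over LE, and over discounted life-years — because
the appropriate denominator is a modelling choice the user should make
explicitly.

## Synthetic data and what passing tests show

The generator emulates a national-registry study: a Gompertz life table
q(a) = 1 − exp(−A·e^{B·a}) with A = 2.5×10⁻⁵, B = 0.10 and a 1.6× male
hazard multiplier (annual mortality ≈ 1.0%/1.6% F/M at age 60, ≈ 4.5%/7% at
75 — realistic adult magnitudes with closed-form checks); diagnosis ages
~N(62, 11²) rounded and truncated to 20–79; two-thirds men; diagnosis years
1998–2016; administrative truncation at a fixed 120 months (a fixed horizon
rather than calendar-date censoring — the simplification only reshuffles
per-patient horizons). Index lifetimes are simulated on the monthly grid
with hazard h = −ln(1−q)/12 plus either an additive monthly excess δ
(default 0.01 — roughly tenfold the referent hazard at 60, an aggressive
malignancy) or a proportional multiplier. The additive default makes true
LE an elementary product-sum, which is computed exactly and shipped with
every cohort as the recovery oracle. Monthly costs are lognormal with mean
450 USD and σ = 1, a ×5 surge over the final 3 months of decedents' lives,
optional per-arm multipliers, re-inflated to nominal TWD at 1%/year CPI so
the adjustment path is exercised. Incidence scenarios draw Poisson counts
around age-specific rates (men roughly twice women, rates doubling across
periods).

Referents are simulated on the annual scheme, index patients on the monthly
scheme; both share annual death marginals and differ only in within-year
timing by under 0.1 month in expectation — negligible against the ~0.1-year
Monte Carlo noise of the estimates.

What the generator does **not** emulate: disease staging and
treatment-switching, random loss to follow-up (administrative censoring
only, by default), secular mortality improvement (the life table is constant
across calendar years), cost heterogeneity beyond the lognormal-plus-surge
shape, and any calibration to a specific cancer's epidemiology beyond orders
of magnitude. Passing recovery tests therefore demonstrate that the
estimator inverts the stated data-generating mechanism at realistic noise
levels — not that it is unbiased for real registry data, where the
logit-ratio trend need not flatten the way a constant excess hazard implies.

## Problem sizes

Validation runs use 2,000 patients, 120-month truncation, 100 referents per
patient and 40–50 bootstrap replicates (seconds to ~1 minute per scenario on
one CPU); unit tests use cohorts of 80–1,500 with 5–30 referents per
patient. Under those conditions the null cohort's recovered loss of LE is
typically within ±0.2 years of zero and the δ = 0.01 cohort's LE within
3–6% of truth; the stratified pipeline applies a minimum stratum size of 50
before attempting extrapolation, since the spline on logit W is unstable for
tiny cohorts.

## Known limitations

- The linear-tail extrapolation of logit W understates survival whenever the
  true ratio trend flattens beyond follow-up (statistical-cure-like
  behaviour is handled well; slowly decaying excess hazards less so).
- SEMs condition on the referent curve and the life table; life-table
  sampling error is not propagated.
- The change-point scan assumes a single terminal cost regime; gradual cost
  ramps longer than `max_L` months are averaged into the stable mean.
- Cost attribution is all-cause: spending on unrelated comorbidity inflates
  the disease's lifetime cost, increasingly so for long survivors.
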