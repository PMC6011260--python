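# Methods

## Backward person-time

Follow-up is retrospective: time runs backwards from the interview date
until the most recent reported injury or until a full injury-free year. The
year is partitioned into eleven 30-day periods and one final 35-day period
(days 330–364), so an uninjured person contributes exactly one person-year
(30/365 to each of months 1–11 and 35/365 to month 12). Conventions:

- Day 0 is the interview day; day d belongs to month `min(d // 30 + 1, 12)`.
  A day exactly on a 30-day boundary goes to the later (more recent) month —
  a half-open-interval choice made for determinism; survey day data are
  rarely precise enough for the choice to matter.
- The injury day itself counts as exposed time (exposure runs up to and
  including the event day), the standard piecewise-exponential convention.
- An injury on the interview day is a degenerate but legal month-1 cell with
  1/365 person-years.
- With a cause filter, injuries of other causes terminate follow-up as
  censoring events without contributing a count.
- Rows with missing covariates are dropped with a logged count; no
  imputation is attempted.

Terminating follow-up at the most recent reported injury makes the monthly
counts the increments of a censored counting process whose hazard at lag t
is the reported-injury rate, so Poisson regression on the censored
person-time remains consistent even though only one injury per person is
recorded. A test quantifies the distortion that would arise *without* the
censoring-aware exposure (naive late-month rates are visibly depressed).

## The likelihood

Cell counts y (per stratum × household × month) are modelled as independent
Poisson variables with mean `PY * exp(x'b + u_h)`, u_h ~ N(0, s^2) a
household random intercept. The marginal likelihood integrates u_h out per
household; we use non-adaptive Gauss–Hermite quadrature centred at 0 with 20
nodes by default (configurable). Two anchors pin the implementation: at
s = 0 the quadrature collapses *exactly* to the independent Poisson
log-likelihood, and on toy tables it agrees with 10,001-node trapezoid
integration over ±8s to 1e-6. Doubling the node count moves the optimized
log-likelihood by < 1e-6 in the default scenarios.

Fitting: fixed-effect-only models use Newton scoring (checked against an
independent IRLS implementation to 1e-6 in coefficients); random-intercept
models start from the GLM solution with s^2 = 0.1 and maximize by L-BFGS-B
with an analytic score, with the boundary s = 0 permitted. Standard errors
come from the observed information (central differences of the analytic
score); when s sits at the boundary the variance block for s is not
reported. An all-zero event table drives the intercept to −∞ and is flagged
as non-convergence rather than returned silently. Rank-deficient designs
raise an error naming the collinear columns.

Time-by-factor interactions are parameterized as one full time curve per
modifier level (dummy × t^j for *every* level), so piecewise specifications
(e.g. quadratic in one group, linear elsewhere) and non-hierarchical models
are directly expressible; predicted rates are invariant to reparameterization
and to the choice of reference levels (tested). Default references: female,
age 16–44, no education, urban, middle tertile — the middle tertile because
tertile relative rates are conventionally reported against it.

Nested models are compared by `lrt`, which verifies nesting by checking that
the smaller design lies in the column span of the larger (this is what makes
a polynomial-in-t model nested in the categorical-month model). AIC is
`2 * n_params - 2 * loglik` with the random variance counted as one
parameter.

Months 1–11 are the default fitting window. Month 12 shows reported rates
well above months 6–11 — consistent with forward telescoping from beyond
the window — and is handled by a separate categorical month-12 vs month-1
model rather than being absorbed into the decay curve.

## Derived decay quantities

The exponential time term, anchored at 1 at t = 0, is read as the
probability that an injury t months old is still reported (only meaningful
while it is decreasing; increasing curves are returned with a warning). The
half-recall time is the smallest t in (0, 11] with polynomial = ln(1/2):
closed form for degrees 1–2 (using the cancellation-free quadratic root
form, stable when the quadratic coefficient is tiny), bracketed root-finding
for degree 3. Times are reported on the t scale, whose origin sits at the
middle of the month preceding the interview; back-substituting published
curve coefficients reproduces the published rounded values on this scale,
which resolves an ambiguity about a possible extra half-month offset
empirically. Window-average rates `(1/t)∫ mu` use closed forms for
exponential decay and polynomial rates (a polynomial averages to the same
degree with the j-th coefficient divided by j+1) and adaptive quadrature
otherwise.

## Rates

Crude rates are `100 * events / person-years` over cumulative windows, with
log-scale Wald intervals `rate * exp(±1.96/sqrt(events))` — chosen because
this form reproduces the published interval for the full data set (481
events, 5365 PY → 8.2–9.8 per 100 PY) where a count-scale Wald interval
does not; zero-event windows return the rule-of-three upper bound, flagged.
Model-based rates weight predicted t = 0 rates by observed month-1
person-years over observed covariate combinations (not a population-standard
grid). Such fits must exclude the random intercept, because population-level
predictions from a frailty model systematically understate marginal rates;
the function enforces this. A delta-method Wald interval from the
coefficient covariance is attached; a clustered bootstrap would be the
more defensible interval in strongly clustered data and is left as an
extension (the Wald SE matches a person-level bootstrap within 15% in an
unclustered simulation).

## The synthetic-data generator

The generator emulates the structure of a Khartoum-style household survey:
households draw a size (mean ≈ 5.8), household-level covariates
(urban:rural ≈ 4.2:1, socioeconomic tertiles in thirds) and a lognormal
frailty; persons draw sex/age/education; true injuries arise as a
homogeneous Poisson process over the 500 days before the interview at the
person's covariate- and frailty-specific rate. Each true injury in the
365-day window is reported independently with the decay probability of the
person's group — making reported injuries a thinned, nonhomogeneous Poisson
process — and each true injury from days 365–499 is, with probability
`telescope_prob`, mis-dated uniformly into month 12 (the simplest mechanism
producing the observed month-12 excess). Only the most recent reported
injury survives into the record.

Reporting is complete (probability 1) throughout month 1 — the same
assumption that lets the model's intercept be read as the true rate — and
decays continuously in days beyond it, with t = (d − 14.5)/30 so that the
mean day of month m sits exactly at the fitted grid point t = m − 1. This
anchoring is what makes the generator and the fitted model agree to first
order: a generator thinning at t = d/30 would shift the fitted grid by half
a month and bias the fitted linear coefficient by the quadratic one, and a
generator clamping a mid-month-anchored curve inside month 1 would make
average month-1 reporting ≈ 0.94 while the model assumes 1. Residual
disagreement (within-month curvature of the exponential) is second-order and
is covered by the parameter-recovery test: over 200 replicated 250-household
cohorts, mean estimates of (b1, b2) fall within 3 Monte-Carlo SEs of the
generating values and 95% Wald coverage is 96–97%.

The survey-scale preset (973 households) uses tertile-specific month-1 rates
of 32.3/16.1/19.3 per 100 PY with the corresponding published log-quadratic
decay curves, frailty SD 0.25 on the log scale ("modest": household rate
multipliers mostly within ±50%), and telescope probability 0.08, chosen so
the expected month-12 reported rate lands near the observed excess. One
preset cohort yields ≈ 5650 persons, ≈ 5400 person-years and ≈ 450–520
reported injuries.

What the generator does *not* emulate: the survey's two-stage cluster
sampling and design weights, nonresponse and proxy-respondent error,
seasonality in true rates, date-heaping, backward telescoping, and
severity-dependent recall. Passing tests therefore demonstrate internal
consistency of the estimation chain under the model's own assumptions, not
robustness to those real-data features.

## Problem sizes and determinism

Simulation tests use 250-household cohorts (200 replicates for recovery) and
single 973-household cohorts for survey-scale demonstrations; these sizes
give Monte-Carlo SEs small enough for 3-SE checks to be informative while
keeping the full suite under a minute. All simulations are driven by
explicit integer seeds through `numpy.random.default_rng`; the same seed
reproduces a cohort byte-for-byte.

## Known limitations

- The decay polynomial is global in t; spline decay for larger data sets is
  a documented extension point, not implemented.
- No overdispersion/quasi-likelihood correction beyond the household random
  intercept, and no survey-weighted likelihood.
- The variance of the model-based overall rate is delta-method only.
- Month-12 inference conflates genuine reporting of old injuries with
  telescoped ones; the generator's telescoping mechanism is one admissible
  formalization, not an identified model.
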