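# recalldecay

Separating true injury rates from memory-decay reporting probabilities in
retrospective household-survey data.

## The problem

Retrospective surveys ask each household about injuries over the past year.
The apparent incidence rate of *reported* injuries falls steeply for events
more than a few months before the interview — not because true rates fell,
but because respondents forget. Crude rates pooled over the full recall
window can understate true incidence by more than half, and if recall decays
faster in some population groups than others, relative rates are distorted
too. This package is for epidemiologists and biostatisticians who need to
quantify, test, and correct for that recall bias.

## The model

Follow-up runs *backwards* from the interview: eleven 30-day periods plus a
final 35-day period (months m = 1..12 before the interview), terminated per
person at the most recent reported injury. The rate of reported injuries is
modelled as

```
lambda(x; t) = lambda0(x) * exp(b1*t + b2*t^2 + b3*t^3),    t = m - 1
```

where `lambda0(x)` is a log-linear function of categorical risk factors
(sex, age group, education, urban/rural, socioeconomic tertile) and the
exponential term — equal to 1 in month 1, where reporting is assumed
complete — is the probability that an injury occurring t months earlier is
still reported. Monthly person-time cells are treated as independent Poisson
counts with log person-time offsets; a household-level normal random
intercept is integrated out by Gauss–Hermite quadrature. Effect modification
of the time term (separate b's per level of a factor) distinguishes
influences on *recall* from influences on *true rates*; because main effects
act at t = 0, non-hierarchical models (interaction without the main effect)
are meaningful. Models are compared by AIC and likelihood-ratio tests, and
decay-corrected absolute rates are obtained by weighting predicted t = 0
rates by month-1 person-years. A synthetic-cohort generator (thinned Poisson
process with group-specific decay, household frailty, and optional forward
telescoping into month 12) makes every step testable.

## Worked example

```python
from recalldecay import *

cfg = khartoum_like_preset(seed=1)            # 973 households, tertile-specific decay
records = generate_cohort(cfg)
table = build_person_time(records)

m1, w = cumulative_crude_rates(table, [[1], range(1, 12)])
spec = ModelSpec(time_modifier="ses_tertile", random_household=False)
res = RecallDecayModel(table, spec).fit()
est = model_based_rate(res, table)
```

This prints (via the calls shown in `res.summary()`, `decay_summary`, etc.):

```
5737 persons, 5411 person-years, 510 reported injuries
crude month-1 rate: 24.0 /100 PY (19.9-28.9)
crude months 1-11:  9.2 /100 PY  -> 62% decline
decay-corrected month-1 rate: 24.0 /100 PY (20.1-27.8)
 group          coefficients  prob_month6  prob_month11  half_recall_months
middle (-0.208945, 0.001905)        0.369         0.150               3.424
 lower (-0.459096, 0.031007)        0.219         0.225               1.706
 upper (-0.21976, -0.010571)        0.256         0.039               2.782
relative rate lower vs middle tertile: 2.01 (1.34-3.01)
```

Reading this: pooling all eleven months understates the month-1 rate by 62%,
while the model-based estimate evaluated at t = 0 recovers it; the lower
socioeconomic tertile forgets fastest (reporting probability falls to one
half after ~1.7 months, vs ~3 in the other tertiles), and with separate
decay curves per tertile the true lower-vs-middle relative rate (generated
as 2.0) is recovered where a shared-decay model would attenuate it.

The same pipeline is scriptable from the shell:

```
recalldecay simulate --preset khartoum --seed 1 --out records.csv
recalldecay build-table records.csv --out table.csv
recalldecay fit table.csv --spec spec.yaml --out fit.json
recalldecay decay-summary --fit fit.json
recalldecay rates table.csv --fit fit.json
```

## Layout

- `recalldecay.cohort` — survey records and backward person-time tables
- `recalldecay.model` — `ModelSpec`, `RecallDecayModel.fit()` → `RecallDecayResults`, LRT/AIC, month-12 comparison
- `recalldecay.decay` — decay curves, half-recall times, window-average rates
- `recalldecay.rates` — crude and model-based absolute/relative rates
- `recalldecay.simulate` — synthetic cohorts and the survey-scale preset
- `recalldecay.reporting` / `recalldecay.cli` — comparison tables and the CLI

See `docs/methods.md` for modelling assumptions, numerical choices, and
limitations.
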