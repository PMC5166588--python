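# Methods notes

## Model and assumptions

The charts treat the case series as an ordered sequence of independent
Bernoulli trials: case *i* fails (a healing abnormality is observed within
follow-up) with probability pᵢ, and the chart asks on which side of a
hypothesis pair the realized sequence falls. The independence assumption
ignores within-surgeon correlation beyond the monotone trend the chart is
looking for, and the binary outcome collapses the severity scale of
graft-healing complications into one flag. The charts are unadjusted: no
covariate enters the score (risk-adjusted CUSUMs are out of scope; the
adjusted analysis lives in the logistic model instead).

Both phases use the same normalized SPRT-derived scheme (README has the
closed forms). The derivation is the Wald approximation: the error rates
α and β are nominal for the one-shot SPRT, and the holding barrier at zero
(which re-arms the test instead of accepting) makes the realized
operating characteristics those of a repeated test — the
`signal_time_monte_carlo` helper exists precisely to estimate the realized
signal fraction and run-length distribution for any scheme, rather than
pretending the nominal α/β are exact.

Direction conventions, chosen once and enforced by types:

* internal scores are positive magnitudes with the barrier at 0 and the
  limit at +h; the learning phase's downward plotting is applied as a sign
  at the trace boundary (`plot_sign`), which keeps the recursion identical
  for both phases and avoids sign bugs;
* the learning phase tests "has the failure rate come *down* to the
  adequate level": the rate favoured by successes is the *smaller* one,
  which for the learning benchmark pair means the nominal p₁ (upper CI
  bound) rather than p₀ — the labels on the learning pair are the reverse
  of the monitoring pair's and the implementation follows the numbers, not
  the labels;
* a case whose update reaches the limit is the signal case (signal "by
  case k" means at k); ties at the limit count as signals within an
  absolute tolerance of 1e−12; barrier truncation happens after each
  update, never mid-update;
* after a proficiency signal the monitoring chart restarts from score zero
  at the *next* case; the signal case itself belongs to the learning phase.

## Parameters that matter

| parameter | meaning | default | why |
|---|---|---|---|
| p₀, p₁ (monitoring) | acceptable / unacceptable failure rates | pooled estimate, upper 95% bound | deterioration is "as bad as the literature's upper bound" |
| p₀, p₁ (learning) | novice / adequate rates | upper bound + 10 pp, upper bound | proficiency means distinguishably better than an inflated novice rate |
| α, β | error rates of the underlying test | 0.05, 0.20 | conventional monitoring choice; h grows as either shrinks |
| lc_offset | learning-phase inflation | 0.10 (10 percentage points, absolute) | the standard benchmark recipe; offset 0 degenerates the scheme and is rejected downstream |
| ci_method | upper-bound construction | exact (Clopper–Pearson) | conservative for small pooled n; `wilson`/`normal` switchable and agree within 1 pp for n ≥ 100 on the tested grid |
| window | early/late split for rates | 49 | the change-point of the default synthetic cohort; any 1 ≤ window ≤ n is accepted |

With the default benchmark inputs (8/76 and 5/48 events), the pooled
estimate is 10.5% and the exact upper bound 17.26%; the chart rates
rounded to printed precision (10.5 / 17.2 / 27.2%) give s = 0.2193,
h = 4.72 (learning) and s = 0.1362, h = 4.85 (monitoring). The all-success
route to proficiency is ⌈h/s⌉ = 22 consecutive clean cases; an unbroken
run of failures in monitoring alarms at case 6.

## Benchmark pooling

"Pooling" is simple event-sum pooling: events and denominators are summed
and treated as one binomial. With two small studies and a rule that only
consumes a point estimate and an upper bound, heterogeneity modelling
(random effects, I²) would be noise; the `ci_method` switch covers the
reasonable uncertainty about how the bound is constructed. When a prior
study is given as a rate, the event count is reconstructed as
round(rate·n) and documented as a reconstruction.

## Logistic model

`fit_healing_model` is a standard ML logistic regression (statsmodels)
of the binary outcome on age, BMI, surgeon case volume (the raw 1-based
order of operation, so the odds ratio is per additional case), operation
time and parity. Wald CIs and p-values are reported — matching the
output style of the mainstream commercial packages this kind of table is
produced with — rather than profile-likelihood intervals. Cox & Snell
R² = 1 − exp[(2/n)(LL₀ − LL₁)] is computed from the fitted and null
log-likelihoods and is exactly 0 for the null model. Complete or
quasi-complete separation raises `ConvergenceError` (detected via the
optimizer's convergence flag and a coefficient-magnitude guard at |b| > 50)
instead of returning an inflated estimate. Rates and the model use the
follow-up-complete subset by default (a patient lost to follow-up can
contribute no observed outcome); `use_all_cases=True` switches to the full
series.

## Synthetic cohorts: what they emulate, and what not

The generator emulates the *structure* of a single-surgeon learning-curve
series: n = 114 cases by default, a change-point failure mechanism
(novice rate 10.2% through case 49, expert rate 0 after — expected event
count 5.0, all in the early window), and covariates drawn independently
from truncated normals at study-like means (age 65.8 ± 7.0 y in [30, 90],
BMI 25.1 ± 3.0 kg/m² in [15, 45], parity 4.0 ± 1.7 rounded and truncated
at [0, 12], operation time 69.1 ± 33.7 min in [10, 240] — the mean is the
case-mix-weighted average of a short mesh-only time of ~37 min and a
longer with-concomitant-procedure time of ~74 min). POP-Q exams carry a
severe preoperative anterior compartment (Ba 2.5 ± 1.6 cm) and a
well-supported postoperative one (Ba −2.8 ± 0.8 cm).

Because a postoperative mean of −2.8 cm sits close to the anatomical floor
of −3 cm, a plain normal draw floored at −3 would recover a biased mean;
the latent mean is therefore moment-matched (solving
E[max(N(μ, σ), −3)] = target) so the floored draw reproduces the target
mean, with a realized point mass at −3 standing in for the many fully
supported exams of a real cohort. The realized SD is correspondingly
slightly below the nominal σ.

What the generator does *not* emulate: correlation between covariates
(none is modelled; a real cohort's BMI/parity/age are not independent),
loss to follow-up (all synthetic records are complete), the exact realized
failure positions of any particular series, and any within-surgeon outcome
dependence beyond the specified pᵢ trend. Tests passing on these cohorts
therefore certify the *machinery* — scheme constants, chart recursions,
estimator behaviour at known generating values — not distributional
claims about real patients.

Seeding: one master seed is split (`SeedSequence.spawn`) into independent
sub-streams for outcomes, covariates and POP-Q draws, so extending the
record schema never perturbs existing draws; byte-identical CSV output is
guaranteed for identical spec + seed.

## Numerical and interface choices

* Scores accumulate in double precision; nothing is rounded until
  presentation (limits printed at 2 dp).
* CSV round-tripping is exact: floats are written at full shortest-repr
  precision and parsed back with the round-trip parser; absent optional
  fields are empty cells, never imputed.
* The deposited-table header vocabulary (`op ordinal`, `erosion`, `0Ba`,
  `1Ba`, `optime`, …) ships as `DATASET_SCHEMA_MAP`; the `erosion` flag is
  mapped to the healing-abnormality outcome (the documented event counts
  match it, as against the broader any-complication column), and
  follow-up completeness is inferred from the presence of a postoperative
  exam when no explicit column exists. Both are stated assumptions.
* Report JSON is validated against a small structural schema shipped in
  `report.py` (required keys and types); reports are reproducible
  bit-for-bit apart from the timestamp.
* CLI exit codes: 0 success, 2 validation error, 3 non-convergence.

## Problem sizes used in the checks

Monte-Carlo and recovery checks run at: 200 replicates of n = 5000 for
odds-ratio recovery and CI coverage (coverage asserted ≥ 90%, point
estimate in [0.94, 0.98] in ≥ 90% of replicates); 500 replicates of
n = 2000 for the ~95% coverage property; 10,000 replicates for the
signal-fraction monotonicity of the learning chart over a 114-case
horizon; exhaustive enumeration of all binary sequences of length ≤ 12
for oracle equivalence of both charts against raw log-likelihood-ratio
accumulation.

## Known limitations

* Nominal α/β are SPRT approximations; realized chart error rates depend
  on the horizon and the holding barrier (use `signal_time_monte_carlo`).
* The anterior-only stage-0 rule (Aa = Ba = −3) ignores the apical points
  C/D that full POP-Q stage 0 also constrains; per-compartment staging is
  the intended scope.
* Replication against the deposited patient-level dataset requires the
  user to supply the CSV (`data/dataset1.csv`); the repository does not
  ship it.
* No risk-adjusted chart, no survival modelling of time-to-erosion, no
  multiple-testing correction, no plotting (the tidy trace CSV is the
  plotting interface).
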