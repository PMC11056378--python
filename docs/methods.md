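# Methods

This note documents the statistical procedures, the data-generating model
behind the synthetic cohorts, the numerical conventions, and the design
choices made where the problem left the design open.

## Episode detection

Heart-rate measurements are binned into half-open hour intervals
[k, k+1) counted from each patient's own ICU admission, and each bin is
summarized by its median (even counts use the mean of the two central
values; empty bins are explicitly missing). Binning is order-invariant by
construction.

**Standard definition.** A patient is peHR-positive when some window of
`window_hours` (default 12) consecutive bins contains at least
`required_hours` (default 11) bins whose median **strictly** exceeds the
threshold (default 100 bpm). "Exceeding" is read literally as `>`; a flat
series at exactly 100 bpm is negative, and the boundary is covered by
tests. Missing bins count as non-exceedance: an episode is never declared
on the strength of unobserved hours. This is conservative — adding missing
bins can only remove positives — and the ≤ 20 % missingness inclusion rule
bounds its impact. The onset is the start of the earliest qualifying
window; note that with an 11-of-12 rule the earliest window may begin one
hour before a long plateau, since one low leading hour is tolerated.

**Extended definition.** Death can censor an episode before a full window
completes. A patient who (a) died during observation, (b) has no completed
qualifying window, and (c) whose final `min_terminal_run` (default 3) or
more *observed* hour bins immediately preceding death all strictly exceed
the threshold, is classified `extended`. A death partway through an hour
can leave that final bin empty, so trailing missing bins are skipped; an
interior missing bin terminates the run. The source analysis never states
a minimum run length; 3 h is a declared floor, exposed in configuration.
Standard status takes precedence when both could apply, and the
`standard_only` mode (the sensitivity analysis) classifies
extended-criterion patients negative.

A deliberately naive window-enumeration oracle ships with the package and
the test suite asserts exact agreement with the vectorized detector on
randomized series across the whole rule grid.

## Cohort rules

Inclusion requires ICU length of stay strictly exceeding 24 h and at most
20 % of hourly bins missing (strictly more than 20 % excludes). The
missingness denominator is the span from admission to the last
observation, or to the hour of death for streams truncated by in-ICU
death; using the observed span avoids penalizing early discharge. One
exclusion reason is logged per subject, first failing rule in the order:
no vitals, length of stay, missingness.

Covariates missing in more than 10 % of subjects are dropped (strict
boundary; outcome, exposure and identifier columns are never dropped).
The remainder are completed by single type-1 predictive-mean-matching
imputation: a least-squares linear predictor of the incomplete variable on
the other covariates is fit on complete cases, and each missing cell
receives the observed value of one of the `k_donors` (default 5, the
conventional count) donors with nearest predicted values; donors tied at
the k-th distance all enter the pool, and sampling is seeded. Imputed
values therefore always lie in the variable's observed support, and
observed cells are never altered. Multiple imputation is deliberately out
of scope — the analysis reports point estimates.

## Survival analysis

Follow-up is administratively censored at 90 days before any model is fit.
Kaplan–Meier curves use the product-limit estimator with ties processed
together and subjects censored at t kept at risk for events at t; the
variance is Greenwood's formula, and curve look-ups are right-continuous.
Group differences use the log-rank chi-square test (k−1 d.f.).

Cox models maximize the partial likelihood with Efron tie handling by
default (Breslow by flag); the day-granularity of a 90-day endpoint can
produce heavy ties, for which Efron is the less biased approximation.
Inference is Wald on the log-hazard scale (HR = exp(β), 95 % CI =
exp(β ± 1.96·se)), matching the HR/CI/p presentation convention; by
construction the CI excludes 1 exactly when p < 0.05. Continuous
covariates enter untransformed (per-unit hazard ratios). Non-finite or
diverging estimates (separation) raise a model-fit error rather than
returning garbage; penalization is out of scope. The fit is cross-checked
in tests against an independent implementation (lifelines) and, on small
samples, against a brute-force maximization of the explicitly enumerated
partial likelihood.

## Propensity-score methods

The propensity model is a maximum-likelihood logistic regression of
exposure on a configurable covariate list, defaulting to age, ventilation
and SOFA — the variables most influential for exposure. "Caliper width of
0.2 logits of the standard difference" is interpreted as the conventional
Austin caliper, 0.2 × SD of the logit propensity score over all subjects.
Matching is greedy 1:1 nearest-neighbour without replacement, processing
exposed subjects in seeded-random order; both the matched and the
stabilized-IPW (ATE) routes are provided because the analysis narrative
describes matching while the balance diagnostics describe weighting, and
both share the propensity model. Balance uses absolute standardized mean
differences — |m₁−m₀|/√((v₁+v₀)/2), with the binomial variance for binary
covariates — computed on the crude, matched, or weighted sample; < 0.1 is
the conventional balance threshold.

## Sensitivity grid

Duration d maps to the rule "d of d+1 consecutive hours", generalizing the
11-of-12 pattern and preserving its one-hour tolerance; whether the
original analysis used "d of d" is not stated, so the mapping is a
declared choice. Thresholds default to 90–120 bpm in steps of 5. Each cell
re-classifies the cohort (extended definition active, terminal-run rule
unchanged) and refits a minimally adjusted Cox model (exposure + age +
ventilation + SOFA). Cells with constant exposure or failed fits are
emitted with a reason code, never dropped. A containment guard verifies
that raising the threshold or duration never adds positives; any violation
is surfaced and fails the test suite.

## Group-comparison table

Continuous variables are displayed as median (IQR) and tested by t-test by
default (ANOVA beyond two groups; Wilcoxon rank-sum by flag) — displaying
medians while testing means mirrors the reporting convention this table
follows, and the test used is named per row. Categorical variables are
n (%) with the chi-square family routed by expected counts: 2×2 tables
with all expected counts ≥ 5 use the continuity-corrected (Yates)
chi-square — the variant that reproduces the reference in-hospital
mortality p ≈ 0.005 on the (30, 351; 53, 311) table, verified against
scipy — 2×2 tables with any expected count < 5 fall back to Fisher's
exact test, and larger tables use plain Pearson chi-square.

## Synthetic cohort generator

The generator is first-class, tested code; its defaults are the study
conditions every acceptance property is evaluated under.

* **Covariates.** Age ~ normal(58, 16) truncated to [18, 95]; weight
  lognormal around 84 kg; SOFA a discretized gamma with median ≈ 5; MAP,
  temperature and SpO₂ normal/gamma around 80 mmHg, 37 °C, 96 %; twelve
  comorbidity flags plus sepsis, ventilation, vasopressor and β-blocker
  use as Bernoulli draws with cohort-realistic marginals. Only the
  marginal shapes matter for exercising the pipeline.
* **Exposure.** Assigned by a logistic model whose covariate effects
  (older age protective, SOFA and ventilation promoting) make the cohort
  confounded; the intercept is solved numerically so the expected marginal
  prevalence equals `episode_prevalence` (default 0.489) exactly.
* **Vitals.** Per-subject baseline heart rate ~ normal(84, 8), kept below
  the tachycardia threshold so unexposed subjects cannot qualify; chart
  entries arrive as a Poisson counting process (default 3/h) with uniform
  within-hour timing, Gaussian noise (default SD 3 bpm), and whole hours
  removed MCAR (default 2 %). Exposed subjects carry one injected plateau
  of 14–40 h whose amplitude (normal(25, 5) bpm, floored at
  threshold + 6 − baseline) guarantees the noise-free signal clears the
  threshold.
* **Survival.** Exponential (constant baseline hazard — the simplest
  proportional-hazards-compatible generator, enabling closed-form checks)
  with hazard λ₀·exp(Σβ(x−x̄) + β_exposure·z), administratively censored
  at 90 days. λ₀ = 0.00125/day is calibrated so cohort-level 90-day
  survival sits near 84 % (unexposed) vs 67 % (exposed) with ≈ 25 %
  overall mortality; the default exposure log-hazard is ln(1.98).
  Continuous covariates are centred at their generating means so effects
  read per unit around a typical patient.
* **Death-truncated episodes.** With probability `death_truncation_prob`
  (default 0.4), an exposed decedent is modeled as dying in the ICU
  mid-tachycardia: the stay extends to the death hour, the vitals stream
  stops there, and the injected run (3–9 h, deliberately too short to
  complete an 11-of-12 window) ends at death. Truncation is applied only
  when the drawn death time is ≥ 26 h, preserving both the ≥ 25 h
  observation-span guarantee and the survival distribution — death times
  are never redrawn, so the realized truncation rate is bounded above by
  the configured probability. Under the defaults this yields an
  extended:standard mix close to the reference cohort's 52:312.
  Non-truncated deaths are treated as occurring after ICU discharge
  (vitals run to the end of the stay), keeping the hazard model exact.
* **Ground truth** records, per subject, whether an episode was injected,
  its interval, and whether death truncated it, enabling
  detector-vs-truth and parameter-recovery experiments.

What the generator does *not* emulate: real charting rhythms and nurse
workflows, correlations between vital signs, treatment feedback (e.g.
β-blockade lowering heart rate over time), informative missingness, or
competing risks. Passing tests therefore demonstrate the pipeline's
internal correctness and statistical calibration under a known model, not
robustness to those real-data phenomena.

## Numerical conventions and problem sizes

All randomness flows from numpy `SeedSequence` spawns of a single integer
seed; identical configuration and seed reproduce every output table
byte-for-byte (CSV floats are written at 10 significant digits; the run
manifest additionally carries a wall-clock timestamp, so reproducibility
is asserted on the CSV bundle). Matching order, PMM donor sampling and
imputation all use seeds derived from the pipeline seed.

Test and acceptance problem sizes are chosen to make binomial/Monte-Carlo
bounds sharp while keeping the default suite quick: 10,000 randomized
series for detector/oracle equivalence, a 2,000-patient cohort for grid
containment, 50 replicates of n = 2,000 for hazard-ratio recovery
(mean within 5 % of the generating HR 1.98; CI coverage in [0.90, 0.99]
at that replicate count), 5,000 subjects for the closed-form KM check, and
2,000 replicates for log-rank type-I calibration.

## Known limitations

* Detection on noisy, gappy series mildly attenuates the pipeline's
  adjusted hazard ratio relative to the generating value (exposure
  misclassification of a few percent); the ground-truth-exposure recovery
  route quantifies the model's own unbiasedness separately.
* Single imputation understates imputation uncertainty by design.
* The propensity "most influential variables" selection step is replaced
  by a configurable covariate list; no regression-tree variable importance
  is computed.
* No multiplicity adjustment across grid cells, no time-varying exposure,
  no competing-risks handling.
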