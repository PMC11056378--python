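# pehr

Prolonged elevated heart rate (peHR) episodes and 90-day mortality in ICU
cohorts.

Sustained tachycardia is a marker of poor prognosis in critically ill
patients, including those with acute pancreatitis. This package implements,
as a tested and reusable pipeline, the full analysis linking peHR exposure
to 90-day mortality:

* **Episode detection** on hourly-median heart-rate series. The *standard*
  definition flags a patient when some window of 12 consecutive hour bins
  contains ≥ 11 hourly medians strictly above 100 bpm. The *extended*
  definition additionally rescues patients whose elevated run was cut short
  by death before a full window could complete; a *standard-only* mode
  serves as the sensitivity analysis.
* **Cohort construction**: aggregation of irregular chart entries to hourly
  medians over half-open hour bins, inclusion rules (ICU stay strictly
  > 24 h; ≤ 20 % of hourly bins missing), screening of covariates with
  > 10 % missing values, and single predictive-mean-matching imputation.
* **Survival analysis**: Kaplan–Meier curves with Greenwood variance,
  log-rank tests, and Cox proportional-hazards models
  (λ(t|x) = λ₀(t)·exp(βᵀx); Efron ties by default, Wald inference) for the
  administratively censored 90-day endpoint.
* **Propensity-score methods**: logistic propensity model, greedy 1:1
  nearest-neighbour matching within a caliper of 0.2 × SD of the logit
  propensity score, stabilized inverse-probability (ATE) weights, and
  standardized-mean-difference balance diagnostics.
* **Sensitivity grid**: exposure re-derived and a minimally adjusted Cox
  model refit for every heart-rate threshold (90–120 bpm) × episode
  duration (6–16 h, as "d of d+1 consecutive hours") combination, with a
  containment guard (stricter criteria can only shrink the positive set).
* **Synthetic cohort generator**: because the source data are a
  credentialed-access clinical database, the package ships a fully
  synthetic ICU cohort generator with known ground truth — irregular
  Poisson-process charting with noise and missing hours, Table-1-like
  covariate marginals, confounded exposure assignment calibrated to a
  target prevalence, exponential proportional-hazards survival, and
  death-truncated episodes that exercise the extended definition.

## Worked example

```python
from pehr import PipelineConfig, SimulationConfig, run_pipeline

cfg = PipelineConfig(simulation=SimulationConfig(n_patients=745, seed=3))
result = run_pipeline(cfg, "out/")
print(result.summary)
```

or from a shell (`pehr run --out out/ --seed 3`), which prints:

```
cohort n=742  prevalence=0.476 (315 standard + 38 extended)
90-day survival: 0.848 (no peHR) vs 0.722 (peHR), log-rank p=1.27e-05
exposure HR: crude 2.02, adjusted 1.85 [1.31, 2.61]
matched pairs max SMD 0.032 (crude 0.401); grid violations 0
```

Reading: about 48 % of the synthetic cohort experienced a peHR episode
(split into standard-window and death-truncated extended positives); their
90-day survival is markedly lower; the Cox hazard ratio adjusted for age,
SOFA, MAP, temperature, sepsis and ventilation sits near the generating
value 1.98; matching brings every covariate below the conventional 0.1 SMD
balance threshold; and the threshold×duration grid has zero containment
violations. The output directory holds the full bundle: exclusion log,
episode calls, Table-1-style summary, KM curves, Cox tables, matched and
weighted diagnostics, sensitivity rerun, grid CSV and a JSON manifest with
file digests.

The `examples/` directory has one short narrative script per capability;
`pehr --help` lists the stage-by-stage CLI.

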