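# alivalid

Partial-validation workflows for an EHR-derived whole-person health index
(allostatic load).  The package covers the full pipeline for studying the
association between the index and healthcare utilization when the index is
computed from error-prone, incomplete records and only a subsample of
patients can be validated by chart review:

- **`ali_core`** — the computable phenotype: ten physiological components
  discretized at clinical thresholds (packaged component table), the index
  as the proportion of non-missing unhealthy components, and roadmap-style
  recovery of missing components from auxiliary chart anchors.
- **`synthetic_cohort`** — a cohort generator with component-level
  misclassification (TPR/FPR), optionally value-dependent missingness, and
  a validation process with configurable recovery, so everything downstream
  is testable without patient data.
- **`validation_designs`** — simple random, case-control, balanced
  case-control, variance-optimal stratified, extreme-tail, and residual
  sampling, plus multi-wave orchestration that never reselects a patient.
- **`smle_inference`** — sieve maximum-likelihood logistic regression: the
  outcome model is fit by EM from validated and unvalidated patients
  jointly, with the exposure error mechanism modelled nonparametrically by
  a B-spline sieve on a finite support grid; profile-likelihood standard
  errors; prediction of the validated index from the fitted error
  mechanism.
- **`audit_tools`** — long-format audit tables, five-category finding
  classification, TPR/FPR/recovery summaries with explicit counts, and
  Fleiss' kappa for inter-auditor agreement.
- **`design_sim`** — the design-selection engine: simulate cohorts across
  data-quality scenarios, apply each candidate design to the same cohorts,
  fit the sieve MLE, and summarize bias/efficiency to recommend the next
  wave's design.

## Command line

Every stage is exposed through one entry point:

```bash
alivalid generate --config generator.yaml --out cohort.csv
alivalid design   --cohort cohort.csv --strategy bcc --n 52 --seed 1 --out ids.csv
alivalid validate --cohort cohort.csv --ids ids.csv --config generator.yaml --out validated.csv
alivalid fit      --cohort validated.csv --out fit.json --fit-out fit_full.json
alivalid predict  --fit fit_full.json --cohort validated.csv --out predicted.csv
alivalid simulate --scenario scenario.yaml --out summary.tsv
alivalid audit-summarize --audit audit.csv --out quality.json
alivalid run-all  --config workflow.yaml --out-dir out/
```

`run-all` executes the whole synthetic workflow (generate, multi-wave
validation — e.g. a 4-patient pilot and two 48-patient waves — final fit
with odds-ratio reporting, predictions, quality summary) and writes a
manifest with the config hash and seed; reruns with the same config are
byte-identical.

Fit reports convert coefficients to presentation scale: baseline odds
`exp(b0)` (index 0, 18 years old), odds ratio per 0.1 index points
`exp(0.1·b1)`, and odds ratio per decade of age `exp(b2)`.

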