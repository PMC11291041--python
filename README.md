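# survpipe

An end-to-end time-to-event prediction pipeline for tabular clinical
cohorts:

- **Piecewise-constant-hazard neural model** — a small seeded MLP mapping
  covariates to one non-negative hazard per time interval, trained on the
  exact piecewise-exponential likelihood (`survpipe.hazard`).
- **Flexible parametric baseline** — a restricted-cubic-spline model on log
  cumulative hazard whose 0-knot special case is exactly Weibull
  proportional hazards (`survpipe.parametric`).
- **Iterative random-forest imputation** — per-column forests visited from
  least- to most-missing, multi-round averaging, include/exclude-outcome
  modes, leakage-safe single-patient imputation for validation rows, and a
  mask-and-score evaluation harness (`survpipe.impute`).
- **Focused-training ensemble** — predict, fine-tune on training patients
  with observed survival within ±70% of the prediction, predict again
  (`survpipe.ensemble`).
- **Model bags and rank-combined selection** — 10 models on random 80%
  subsamples aggregated by pointwise-median curves; staged nested
  hyperparameter search ranked jointly on concordance, median absolute
  difference and its time-normalised variant (`survpipe.bagging`,
  `survpipe.tuning`, `survpipe.evaluate`).
- **Counterfactual treatment choice** — a quartile grid of synthetic
  patients and the treatment level maximising each patient's predicted
  median survival (`survpipe.counterfactual`).
- **Synthetic cohorts** — generators with skewed survival, covariate-driven
  hazards, administrative censoring and MCAR/MAR/outcome-dependent
  missingness, plus presets for an ALS-like and an AF-like cohort
  (`survpipe.simulate`).

The model is implemented in pure numpy (no deep-learning framework is
required); training is bit-reproducible for a fixed seed.

## CLI

Everything is reachable through one entry point:

```bash
# generate a synthetic ALS-like cohort with a schema file
survpipe simulate --preset als --n 2000 --seed 1 \
    --out cohort.csv --schema-out schema.yaml --truth-out truth.csv

# impute missing covariates (10 averaged rounds by default)
survpipe impute --in cohort.csv --schema schema.yaml \
    --rounds 10 --exclude-outcome --seed 1 --out imputed.csv

# train a 10-model bag and predict median survival
survpipe train --in imputed.csv --schema schema.yaml --out-dir model/ \
    --hidden 32 --epochs 200 --m 10 --seed 1
survpipe predict --model model/ --in imputed.csv --schema schema.yaml \
    --out predictions.csv

# focused-training ensemble prediction
survpipe predict --model model/ --in imputed.csv --schema schema.yaml \
    --ensemble --train-cohort imputed.csv --window 0.7 --extra-epochs 200 \
    --min-cohort 50 --out predictions.csv

# metrics, hyperparameter search, counterfactual treatment choice
survpipe evaluate --pred predictions.csv --truth imputed.csv \
    --schema schema.yaml --out metrics.json
survpipe tune --in imputed.csv --schema schema.yaml --grid grid.yaml \
    --seed 1 --out tuning.json
survpipe counterfactual --model model/ --in imputed.csv \
    --schema schema.yaml --treatment-col doac --out recommendations.csv

# or the whole pipeline from one YAML config
survpipe run --config run.yaml --out-dir out/
```

`survpipe run` writes every artifact (cohort, imputed table, model card,
predictions, metrics) plus a structured JSON-lines audit log proving that
validation rows only pass through single-patient imputation and frozen
encoders.

A `run.yaml` looks like:

```yaml
seed: 1
cohort: {preset: als, n: 2000}   # or a path to a cohort CSV (+ schema:)
split: 0.8
imputation: {rounds: 10, max_iterations: 10, trees: 100, include_outcome: false}
model: {hidden: [32], learning_rate: 0.01, epochs: 200, m: 10, bag_size: 10}
ensemble: {enabled: true, window: 0.7, extra_epochs: 200, min_cohort: 50}
```

## Schema files

Cohort CSVs are described by a YAML schema: one block per column with
`name`, `kind` (`duration`, `event`, `continuous`, `categorical`,
`treatment`), `units` for the duration column and `levels` for
categorical/treatment columns. Missing cells are empty strings or `NA`.
Rows missing duration or event are dropped at read time; missing covariates
are kept for imputation.
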