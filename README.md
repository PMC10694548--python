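# chaincv

A tested, reusable evaluation pipeline for multi-label prediction of
comorbid disorders from tabular morphometric features, exercised entirely
on synthetic cohorts:

- **`chaincv.synthetic_cohort`** — latent-liability cohort simulator:
  correlated comorbidity, confounder-driven feature variance, sibling
  families, two-informant diagnostic reports with configurable
  sensitivity/specificity, and completely-at-random missingness.
  Named presets: `null`, `confounded`, `signal`, `paper_like`.
- **`chaincv.cohort_assembly`** — participant selection flow (missing
  features → missing diagnoses → one random child per family, with an
  auditable ledger) and OR-rule label derivation over multi-informant,
  multi-time-state reports, including composite disorder definitions.
- **`chaincv.confound_adjust`** — per-feature OLS residualization on an
  encoded sociodemographic design (standardized continuous, one-hot
  categoricals), with leakage-safe per-split and global modes.
- **`chaincv.models`** — logistic baseline (LRC), gradient-boosted
  classifier-chain ensembles (CCE: 10 chains × one member per disorder,
  random orderings, teacher forcing at train time, hard-label passing at
  inference), independent per-disorder GBMs, and a Gaussian-process
  sequential hyperparameter tuner.
- **`chaincv.evaluation`** — repeated multi-label stratified K-fold CV
  (iterative stratification; 30×5 = 150 splits at the paper profile),
  rank-based AUROC, Youden-J operating points, balanced accuracy,
  sensitivity, specificity; per-split metrics averaged, never pooled.
- **`chaincv.significance`** — label-permutation null distributions of
  mean AUROC (fresh split plan and model seeds per replicate), p =
  (exceedances + 1)/B, Bonferroni family-wise control.
- **`chaincv.pipeline` / `chaincv.cli`** — config-driven orchestration
  with deterministic seed fan-out and CSV outputs throughout.

## CLI

```sh
chaincv plan --profile paper            # dry-run job accounting
chaincv run-all --config config.yaml    # simulate → … → report
chaincv simulate --scenario paper_like --out runs/demo
```

Stages (`simulate`, `assemble`, `residualize`, `evaluate`, `permtest`,
`report`) are independently invokable against the same run directory.
A config file is plain YAML mirroring `chaincv.pipeline.RunConfig`;
the `desk` profile (2×5 CV, B=99, n≈1000) is the default, and the
`paper` profile (30×5 CV, B=500) prints a cost warning — it schedules
2 models × 10 disorders × 501 evaluations × 150 splits.

Example config:

```yaml
scenario: confounded      # preset name or scenario YAML path
residualization: per_split
models: [lrc, gbm_cce]
n_repeats: 2
n_folds: 5
n_permutations: 99
master_seed: 7
out_dir: runs/confounded
```

## Reproducibility

Every stochastic component is driven by `numpy.random.SeedSequence`
fan-out from a single master seed; re-running a pipeline config
reproduces every CSV byte-for-byte (tested).
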