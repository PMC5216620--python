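# connage

Seed-based sensorimotor functional-connectivity analysis and connectome-based
age prediction, exercised end-to-end on synthetic cohorts with known ground
truth.

The package implements, as reusable tested components:

- **`connage.synthetic`** — cohort generator: subject tables (age, gender,
  education, gray-matter volume), node time series with prescribed age- and
  group-dependent correlation structure (insula↔M1/S1 edges declining with
  age in the older group, M1/S1↔superior-parietal edges shifted upward), and
  random-walk motion traces with a configurable high-motion fraction.
- **`connage.qc`** — framewise displacement (translation/rotation triplets,
  mean Euclidean norm of successive differences), motion-based exclusion
  (strict 1 mm / 1° thresholds), zero-phase Butterworth band-pass
  (0.01–0.08 Hz) and nuisance regression with optional global-signal
  removal.
- **`connage.connectivity`** — seed signals, Pearson correlation maps with
  Fisher r-to-z transform, plus a volume-mode adapter (spherical seeds on a
  NIfTI grid).
- **`connage.group_stats`** — per-group covariate residualization,
  one-sample and pooled two-sample t-tests under an explicit union mask,
  Benjamini–Hochberg FDR, strict cluster-extent filtering, and
  altered-connectivity feature extraction.
- **`connage.prediction`** — UVPA (leave-one-out simple regression on one
  feature) and MVPA (nested leave-one-out loops: inner correlation-ranked
  feature-count selection, consensus features, linear ε-SVR with ε = 0.001),
  with label-permutation significance using the +1-corrected exceedance
  p-value. The SVR is a small deterministic dual coordinate-descent solver
  (`connage.svr`), validated against liblinear in the test suite.
- **`connage.classification`** — older-vs-younger linear SVM with LOOCV,
  accuracy / sensitivity / specificity and a Mann–Whitney-consistent
  ROC/AUC.
- **`connage.pipeline` / `connage.cli`** — stage orchestration with
  per-stage manifests (parameter echo + input/output hashes) and a click
  CLI.

## CLI

```sh
connage simulate --config config.yaml --out run/ --seed 1
connage qc --out run/
connage connect --out run/ --gsr          # or --no-gsr
connage stats --out run/ --q 0.05 --cluster-k 23
connage predict --out run/ --mode mvpa --n-perm 199 --seed 1
connage predict --out run/ --mode uvpa --feature "Ins.L and M1.L"
connage classify --out run/
connage report --out run/
connage all --config config.yaml --out run/ --seed 1
```

Configuration is a single YAML file with per-stage sections
(`simulate`, `qc`, `connect`, `stats`, `predict`, `classify`); CLI flags
override file values. Exit codes: 0 ok, 2 configuration error, 3 stage
error. Every stage writes a `manifest_<stage>.json` so identical configs can
be verified to reproduce byte-identical outputs.

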