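# icrpipe

Consensus-clustering immune classification of NSCLC expression cohorts,
with companion immune-signature scoring, outcome-association statistics and
survival analysis. A synthetic multi-cohort generator with a planted
four-class immune continuum makes the whole pipeline testable without any
patient data.

## What it does

* **`synthetic_data`** — generates multi-cohort log2 expression matrices
  (20-gene ICR panel + correlated companion-signature genes + fillers),
  clinical tables (DCB outcome, disease-free survival), per-cohort batch
  effects, and a raw NanoString-style 770-probe count fixture with known
  scale factors and background.
* **`nanostring_norm`** — nSolver-style processing of raw probe counts:
  background subtraction (geometric mean of negative controls),
  geometric-mean scaling to positive-control + housekeeping probes, log2.
* **`harmonize`** — per-cohort quantile normalization, per-cohort gene
  standardization (used for CD274/PDL1), pooling of per-patient tables.
* **`icr_classifier`** — consensus clustering of the 20-gene ICR panel
  (item resampling, Ward.D2 inner / complete outer linkage, k = 4),
  ICR score (mean panel log2), score-ordered relabeling ICR1..ICR4 and
  collapsing to ICR1 vs ICR2-4.
* **`signatures`** — GMT-backed metagene scores (immune-cell subsets,
  pathway activation, APM), cytolytic activity, TIS, TLS, Th1/Th2 ratio,
  standardized CD274, and first-quintile low/high binarization.
* **`association`** — contingency tables, Wald odds ratios, exact 2×k
  conditional tests by enumeration, IRLS logistic regression with Wald
  intervals, one-way ANOVA, Cochran's Q cross-cohort homogeneity.
* **`survival`** — Kaplan-Meier with Greenwood CIs, k-sample log-rank.
* **`pipeline_cli`** — end-to-end orchestration and a JSON report
  (class proportions, DCB rates, ORs/CIs, homogeneity, log-rank).

## CLI

```sh
icr simulate --seed 1 --cohorts 5 --sizes 44,30,30,28,30 --out sim/
icr classify --expr sim/cohort0_expression.tsv --reps 5000 --pitem 0.8 --seed 1 --out labels.csv
icr score --expr sim/cohort0_expression.tsv --out scores.csv
icr normalize-nanostring --counts counts.csv --out expr.tsv
icr survival --data surv.csv --out km/
icr run-all --seed 1 --reps 5000 --out run/      # or: icr run-all --config run.yaml
icr check-reference                               # verify engine vs published counts
```

`run-all` writes `patients.csv` (pooled per-patient table), `association.csv`,
per-group Kaplan-Meier curves, `summary.json` (deterministic given the seed)
and `run.log`.

## Notes

* All per-cohort steps (normalization, classification, scoring,
  binarization) run separately per cohort; only labels and scores are
  pooled.
* Shipped gene-set member lists (`src/icrpipe/data/signatures.gmt`) are
  editable surrogates; replace them with your own GMT via `icr score --gmt`.
* Consensus clustering results are invariant to input column order and
  deterministic given the seed.
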