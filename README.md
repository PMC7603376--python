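# omisurv — multi-omics parallel-integration survival subtyping

`omisurv` implements a deep-learning multi-omics subtyping pipeline for
cancer cohorts (the motivating setting is non-small-cell lung cancer with
six omics categories: mRNA, miRNA, DNA methylation, CNV, somatic mutation
and RPPA protein arrays). It is aimed at computational biologists who want
to discover survival-associated patient subtypes from several omics layers
at once, then predict those subtypes for patients with only one layer
measured.

## Method

Each omics category is compressed **in parallel** by its own autoencoder
(dense 500–100–500 tanh layers, dropout 0.5, SGD with MSE loss) into a
shared 100-dimensional latent space. Latent features are screened per
category with univariate Cox proportional-hazards models,
h(t) = h₀(t)·exp(βx), keeping features with score-test *p* < 0.01 plus at
most the top three with 0.01 ≤ *p* < 0.05. The selected features from all
categories are merged by sample id into the *integration matrix*, clustered
by k-means (K chosen by silhouette, Calinski–Harabasz as tie-breaker, elbow
curve reported), and the cluster labels are ordered by Kaplan–Meier median
survival so that subtype 1 survives longer. Per-category L2-logistic
classifiers (C = 1) then predict the integration subtype from a single
omics layer, transferring labels to samples missing the other layers; a
log-rank test on the transferred labels validates the subtype out of
cohort. Finally, two gradient-boosted tree models fit on the uncompressed
protein matrix are decomposed with exact path-dependent Shapley values to
rank subtype-driving proteins, and a single-omics baseline (the same
pipeline without the autoencoder, on one matrix) quantifies what the
integration adds.

Because real multi-omics cohorts cannot ship with the package, a
first-class synthetic generator produces cohorts with a latent two-level
subtype driving exponential survival times (hazard ratio HR, independent
uniform censoring; median survival ln2/λ per arm) and per-category feature
signal of configurable strength — strong in RPPA, weak in
mRNA/miRNA/methylation, absent in CNV/somatic mutation by default.

## Worked example

```bash
python analysis/01_simulate_cohort.py   # writes scratch/cohort/
python analysis/02_run_pipeline.py      # full pipeline, tables + figures in results/
python analysis/03_null_calibration.py  # calibration under the global null
```

On the default cohort (600 common samples, 200 RPPA-only samples, HR = 2)
the second script prints:

```
chosen K = 2; ARI vs truth = 0.840
common-cohort log-rank p = 2.58e-11; subtype-histology chi-square p = 0.64
        category  auc_mean   auc_sd
            mRNA  0.524677 0.035660
           miRNA  0.598399 0.044950
     methylation  0.592190 0.021631
             CNV  0.489311 0.024888
somatic_mutation  0.524920 0.042904
            RPPA  0.998100 0.001561
RPPA uncommon transfer: log-rank p = 0.00295
xgboost_like: top-5 proteins ['RPPA_f0079', 'RPPA_f0110', 'RPPA_f0136', 'RPPA_f0113', 'RPPA_f0066'] (5/5 truly informative)
lightgbm_like: top-5 proteins ['RPPA_f0079', 'RPPA_f0136', 'RPPA_f0110', 'RPPA_f0113', 'RPPA_f0066'] (5/5 truly informative)
```

Reading: k-means recovered the latent subtype (adjusted Rand index 0.84)
and chose K = 2 unaided; the subtype splits survival decisively on the
common cohort while staying independent of histology; only the
protein-layer classifier can predict the subtype from a single layer
(AUC 0.998 vs ≈ 0.5 for CNV/mutations), and the labels it transfers to the
200 protein-only samples still separate survival (p = 0.003). Both
gradient-boosting presets rank exactly the five truly signal-bearing
proteins at the top.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

re-runs the whole pipeline from scratch on the default synthetic cohort —
simulation, compression, screening, clustering, transfer and attribution —
prints the summary above and writes the JSON report to `--out`.

## Layout

- `src/omisurv/` — the library: `io_preprocess`, `synthetic`, `compression`
  (numpy autoencoder), `survival_stats` (Cox score test, Kaplan–Meier,
  log-rank, association tests), `feature_selection`, `clustering`,
  `transfer`, `attribution` + `treeshap`, `pipeline`, `plots`.
- `analysis/` — numbered narrative drivers over the library.
- `tests/` — unit, property and acceptance suites.
- `docs/methods.md` — modelling assumptions, parameter choices, limitations.
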