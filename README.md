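# metaboselect

Untargeted LC-MS metabolomics produces peak tables of thousands of
features over modest sample panels, contaminated by injection-order drift
and batch effects, and the question "which signals discriminate my sample
groups?" is notoriously easy to answer wrongly — selecting features on the
same data used to evaluate them inflates apparent accuracy (selection
bias). `metaboselect` implements, as a tested Python library, the full
chain used in cultivar-classification studies of this kind:

1. **Pre-treatment** — iterative random-forest imputation of missing peak
   areas; pooled-QC based signal correction, where a per-feature
   gradient-boosted model trained on QC injections (covariates: injection
   order, batch) predicts the expected intensity and every cell becomes
   `S_corrected = S_observed / S_predicted × 1000`; removal of features
   with QC RSD > 30%; technical-replicate averaging; autoscaling; and
   column-binding of positive- and negative-mode tables.
2. **Metabolome-based classification** — samples are clustered in the
   space of their first 10 principal components by Ward.D2 linkage on
   Manhattan distances and the dendrogram is cut into two groups; these
   cluster labels, not external annotations, are the classes used
   downstream.
3. **Nested marker selection** — a three-criterion "rational cut-off"
   (BH-adjusted moderated-t p < 0.05, |log2 fold change| > 1, PLS VIP > 1)
   applied inside a nested resampling scheme: stratified 10-fold outer
   cross-validation; per outer fold, nine inner iterations whose training
   sets are bootstrapped five times; strict intersection of the selected
   sets within and across folds; logistic-GLM validation of each outer set
   on its held-out fold. The final marker set is the intersection over all
   outer folds, reported with retention-time grouping.

The moderated t-test (empirical-Bayes variance shrinkage), BH step-up,
NIPALS PLS1 with VIP, Q²-based component tuning with permutation testing,
ridge-IRLS logistic GLM, SVD PCA and Ward.D2/Lance–Williams clustering are
implemented in-package and verified against independent oracles
(limma-style closed forms, scikit-learn, scipy, statsmodels) in the test
suite. A fully seeded synthetic-study generator reproduces the assumed
design — 18 cultivars × 3 biological × 2 technical replicates in 9 batches
with 5 QC + 3 blank injections each, smooth drift, batch offsets, pooled
QC composition, planted group markers and intensity-censored missingness —
so every stage is testable without any download.

## Worked example

```python
import numpy as np
from metaboselect import (SimulationConfig, simulate_study, pretreat_study,
                          PretreatmentConfig, assign_metabolome_labels,
                          run_nested_selection, build_marker_table,
                          adjusted_rand_index)

cfg = SimulationConfig(n_features_pos=100, n_features_neg=100,
                       n_markers=20, marker_log2_effect=2.0, seed=7)
pos, neg, truth = simulate_study(cfg)
result = pretreat_study(pos, neg, PretreatmentConfig(seed=7))
print("analysis table:", result.table_raw.n_samples, "samples x",
      result.table_raw.n_features, "features")

assignment = assign_metabolome_labels(result.table_scaled,
                                      raw_table=result.table_raw)
labels = assignment.label_array()
print("ARI vs planted groups:",
      round(adjusted_rand_index(labels,
            truth.group_labels(result.table_scaled.samples)), 3))

selection = run_nested_selection(result.table_scaled, result.table_raw,
                                 labels, seed=7)
print("outer GLM accuracies:", selection.outer_accuracies)
markers = build_marker_table(selection, result.table_raw,
                             result.table_scaled, labels, seed=7)
print(markers.head(3).to_string(index=False))
planted = truth.marker_ids_bound()
print(f"recovered {len(selection.final_set & planted)} planted markers, "
      f"{len(selection.final_set - planted)} false positives")
```

prints (about a minute on one core):

```
analysis table: 54 samples x 200 features
ARI vs planted groups: 1.0
outer GLM accuracies: [1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0]
feature_id polarity       mz     rt      vip  log2_fold_change  rt_group
 neg_N0084 negative 715.1431  3.274 2.339260          2.071511         1
 neg_N0078 negative 455.3269  4.373 2.687729          2.455872         2
 pos_P0063 positive 142.1108 12.880 2.421146          2.405336         3
recovered 18 planted markers, 0 false positives
```

The 108 study injections per polarity collapse to 54 analysis rows after
technical averaging; the two-group clustering recovers the planted 8/10
cultivar split exactly (adjusted Rand index 1.0); each of the ten held-out
outer folds is classified perfectly by a GLM restricted to that fold's
selected features; and the final intersected marker set contains 18 of the
20 planted markers with zero noise features, each reported with its m/z,
retention time, polarity, full-dataset VIP and log2 fold change, and a
retention-time group id.

A command-line interface mirrors the stages
(`metaboselect simulate | pretreat | classify | select | report |
run-all`, with `--config`, `--seed`, `--log-level`); all tabular outputs
are CSV, selection results and ground truth JSON.

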