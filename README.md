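# crtpredict

A pipeline for predicting multi-class tumor-regression response to
preoperative chemoradiotherapy from gene-expression profiles. It implements:

- **Feature scoring** of one-vs-rest binary contrasts (TO-vs-rest,
  MI-vs-rest) with a Welch t-test p-value and a log2 mean-difference effect
  size, combined into three per-gene feature scores: `pval` = −log10(p),
  `rank` = rank(−log10 p) × rank(|d|), and `norm` = minmax(−log10 p) ×
  minmax(|d|).
- A **classifier bank** of seven binary algorithms behind one train/predict
  contract: linear SVM, random forest, elastic-net logistic regression,
  LDA, and kNN with k = 1, 3, 5.
- **Model selection** by stratified 5-fold cross-validation over the grid
  feature-score type × feature count × algorithm, with two scoring modes:
  `paper` (feature scores computed once on the whole cohort — optimistically
  biased, kept deliberately) and `nested` (scores recomputed within each
  training split).
- **Sequential multiclass prediction**: the TO model is applied first; TO-
  negative samples go to the MI model; double negatives are labeled MO
  (which absorbs NT throughout evaluation).
- **Cross-platform harmonization** for external validation: gene-symbol
  matching, reference-based quantile normalization (each external sample's
  rank-r value is replaced by the reference's mean r-th order statistic over
  the common genes), and model rebuild on the common-gene intersection.
- **Evaluation**: 3×3 confusion matrix (predicted rows × true columns over
  {MI, MO, TO}), per-class sensitivity, and overall accuracy, reported as
  percentages to one decimal.
- A **synthetic-cohort generator** (default: 2000 genes × 77 samples with
  grade counts 10 MI / 36 MO / 13 NT / 18 TO, planted TO- and MI-specific
  differentially expressed gene sets) and a platform-distortion simulator,
  so the whole pipeline is testable without patient data.

## CLI

All stages are exposed as `crtpredict` subcommands:

```sh
# synthetic cohort (expression.tsv, labels.tsv, truth.tsv + optional
# second-platform matrix)
crtpredict simulate --seed 1 --out-dir data/ --distort

# per-gene feature table for one contrast
crtpredict score --expr data/expression.tsv --labels data/labels.tsv \
    --target TO --out to_table.tsv

# cross-validated grid and best-cell selection
crtpredict select --expr data/expression.tsv --labels data/labels.tsv \
    --target TO --fs-types pval,rank,norm --feature-counts 2-100 \
    --algorithms svm,rf,en,lda,knn1,knn3,knn5 --seed 1 \
    --out-grid grid.tsv --out-summary summary.tsv

# train / predict a single binary model
crtpredict train --expr data/expression.tsv --labels data/labels.tsv \
    --target TO --features-file features.txt --algorithm svm --out to.json
crtpredict predict --model to.json --expr data/expression.tsv --out preds.tsv

# external validation: harmonize a second platform, rebuild on common genes
crtpredict harmonize --ref data/expression.tsv \
    --ext data/expression_platform2.tsv --out-dir harm/
crtpredict rebuild --expr data/expression.tsv --labels data/labels.tsv \
    --to-features to_genes.txt --mi-features mi_genes.txt \
    --common harm/common_genes.txt --out seq.json

# three-class prediction and evaluation
crtpredict predict-multiclass --model seq.json --expr harm/mapped.tsv \
    --out mc_preds.tsv
crtpredict evaluate --pred mc_preds.tsv --labels data/labels.tsv \
    --out-matrix cm.tsv --out-report report.txt
```

## File formats

- **Expression matrix**: tab-delimited UTF-8; header row `gene<TAB>sample ids...`;
  one gene per row. Values are written with full `repr` precision so a
  write/read round trip is exact.
- **Labels**: two-column TSV (`sample_id`, `grade`) with header. Grades are
  accepted as `MI/MO/NT/TO`, numeric `1–4`, or `G1–G4` (case-insensitive);
  grade 0 is rejected.
- **Models**: versioned self-describing JSON envelopes
  (`crtpredict-binary-model` / `crtpredict-sequential-model`, version 1)
  holding the algorithm id, feature gene list, contrast, seed, and the
  fitted estimator as base64-encoded pickle bytes.

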