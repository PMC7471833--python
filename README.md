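# shapsel

Cross-fold Shapley-value stability selection and benchmarking for
multiscale (mRNA + microRNA) expression data, with a synthetic-data
generator so the whole pipeline is testable without any download.

## What it does

- **`shapsel.syndata`** — log-normal synthetic expression datasets with a
  planted, direction-alternating class signal in two feature blocks of
  very different widths, plus a ground-truth sidecar for
  parameter-recovery experiments.
- **`shapsel.io_prep`** — tab-delimited readers/writers, per-block
  normalization (log2 + train-fitted z-score), a per-feature two-sample
  t-test filter (p < alpha, train samples only), seeded train/test
  splitting, and provenance-preserving block concatenation
  (`mRNA:`/`miRNA:` prefixes).
- **`shapsel.rankers`** — five classical feature rankers: log2 fold change
  (with directional top-n/2 extraction), OneR, ReliefF, InfoGain and
  GainRatio, plus deterministic top-n selection.
- **`shapsel.shapley`** — Shapley values for black-box classifiers under a
  marginal (background-averaged) coalition value: an exact
  subset-enumeration oracle (width-capped), an unbiased Monte-Carlo
  permutation estimator, and an exact linear-time tree-path evaluator for
  sklearn tree ensembles (numba-accelerated). All three routes agree to
  numerical precision and satisfy the additive decomposition
  `phi0 + sum(phi) = f(x)` per instance.
- **`shapsel.stability`** — the selection strategy: K stratified folds;
  per fold, fit a forest on the training portion and score each feature by
  the sum of absolute Shapley values over the training samples; keep each
  fold's top-k as a binary flag; sum flags into per-feature fold counts
  `F_y`; select features with `F_y` strictly above the threshold
  (defaults: K = 10, top 300, threshold 5).
- **`shapsel.evalbench`** — ACC / MCC / F1 from confusion counts, a
  pluggable classifier contract with two reference classifiers (random
  forest, logistic regression), a leakage-safe dataset preparation step,
  and a resumable factorial benchmark grid (feature type x selector x
  classifier x seed) with tidy TSV output and group-wise summaries.

## CLI

```sh
shapsel simulate --n-samples 200 --seed 1 --out data/
shapsel rank --expression data/mrna_expression.tsv --labels data/labels.tsv \
    --method infogain --top-n 50
shapsel select-shap --mrna data/mrna_expression.tsv --mirna data/mirna_expression.tsv \
    --labels data/labels.tsv --block combined --seed 1 \
    --out-selected selected.tsv --out-profile profile.tsv
shapsel benchmark --mrna data/mrna_expression.tsv --mirna data/mirna_expression.tsv \
    --labels data/labels.tsv --config run.yaml --results results.tsv
shapsel summarize --results results.tsv --by selector,feature_type
shapsel evaluate --predictions pred.tsv --labels data/labels.tsv
```

## File formats

- Expression matrix: tab-delimited UTF-8; header `feature_id` followed by
  sample ids; one row per feature; raw values must be nonnegative.
- Labels: tab-delimited `sample_id`, `label` (label strings configurable,
  mapped to positive/negative).
- Ground-truth sidecar: `feature_id`, `block`, `informative` (0/1),
  `direction` (+1/-1).
- Stability profile: `feature_id`, `F_y`, one 0/1 column per fold.
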