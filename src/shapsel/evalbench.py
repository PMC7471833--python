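"""Classifier harness, evaluation metrics and the benchmark grid.

The grid axes mirror the study design: feature type (mRNA, miRNA,
combined) x selector (the five classical rankers at each top-n, the
Shapley stability selector, or all features) x classifier x seed. Two
reference classifiers ship built-in — a randomized-tree ensemble and a
regularized logistic baseline — behind a pluggable spec, so further
algorithms can be added without touching the runner.
"""

from __future__ import annotations

import logging
import os
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as _scipy_stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression

from . import rankers as _rankers
from .io_prep import (
    ExpressionBlock,
    SampleLabels,
    SplitAssignment,
    combine_blocks,
    normalize_block,
    split_train_test,
    ttest_filter,
)
from .shapley import SklearnProbaModel

logger = logging.getLogger(__name__)

SCHEMA_HEADER = "# shapsel-benchmark v1"
METRIC_COLUMNS = ["acc", "mcc", "f1"]


# ---------------------------------------------------------------------------
# metrics


@dataclass
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "tn", "fp", "fn"):
            v = getattr(self, name)
            if v < 0 or int(v) != v:
                raise ValueError(f"{name} must be a nonnegative count, got {v}")
            setattr(self, name, int(v))

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class MetricSet:
    acc: float
    mcc: float
    f1: float


def confusion(predicted: np.ndarray, true: np.ndarray) -> ConfusionCounts:
    predicted = np.asarray(predicted)
    true = np.asarray(true)
    if predicted.shape != true.shape:
        raise ValueError("predicted and true label vectors must align")
    if predicted.size == 0:
        raise ValueError("cannot build a confusion matrix from empty input")
    for name, arr in (("predicted", predicted), ("true", true)):
        bad = set(np.unique(arr)) - {0, 1}
        if bad:
            raise ValueError(f"unknown {name} label values: {sorted(bad)}")
    tp = int(np.sum((predicted == 1) & (true == 1)))
    tn = int(np.sum((predicted == 0) & (true == 0)))
    fp = int(np.sum((predicted == 1) & (true == 0)))
    fn = int(np.sum((predicted == 0) & (true == 1)))
    return ConfusionCounts(tp, tn, fp, fn)


def accuracy(c: ConfusionCounts) -> float:
    if c.total == 0:
        raise ValueError("empty confusion matrix")
    return (c.tp + c.tn) / c.total


def mcc(c: ConfusionCounts) -> float:
    """Matthews correlation; the 0/0 case is defined as 0 (uninformative)."""
    if c.total == 0:
        raise ValueError("empty confusion matrix")
    denom = (
        (c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn)
    )
    if denom == 0:
        return 0.0
    return (c.tp * c.tn - c.fp * c.fn) / float(np.sqrt(denom))


def f1(c: ConfusionCounts, empty_value: float = 1.0) -> float:
    """F1 = 2TP / (2TP + FP + FN); with no positives anywhere (TP = FP =
    FN = 0) the score is vacuously perfect, ``empty_value`` (default 1)."""
    if c.total == 0:
        raise ValueError("empty confusion matrix")
    denom = 2 * c.tp + c.fp + c.fn
    if denom == 0:
        return empty_value
    return 2 * c.tp / denom


def metric_set(c: ConfusionCounts) -> MetricSet:
    return MetricSet(accuracy(c), mcc(c), f1(c))


def welch_compare(a, b) -> tuple[float, float]:
    """Unequal-variance t statistic and p-value for comparing two metric
    distributions (e.g. MCCs of two model variants)."""
    res = _scipy_stats.ttest_ind(np.asarray(a, float), np.asarray(b, float), equal_var=False)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# classifiers


@dataclass
class ClassifierSpec:
    """Pluggable classifier contract: a registered name, hyperparameters
    and a seed. Fitting is deterministic given the seed."""

    name: str = "random_forest"
    params: dict = field(default_factory=dict)
    seed: int = 0


def _build_classifier(spec: ClassifierSpec, seed: int):
    if spec.name == "random_forest":
        return RandomForestClassifier(random_state=seed, n_jobs=1, **spec.params)
    if spec.name == "logistic":
        params = {"max_iter": 2000, **spec.params}
        return LogisticRegression(random_state=seed, **params)
    raise ValueError(f"unknown classifier {spec.name!r}; available: random_forest, logistic")


def fit_model(spec: ClassifierSpec, X: np.ndarray, y: np.ndarray, seed_offset: int = 0):
    clf = _build_classifier(spec, spec.seed + seed_offset)
    clf.fit(np.asarray(X, float), np.asarray(y, int))
    return SklearnProbaModel(clf)


def fit_predict(
    spec: ClassifierSpec,
    train_block: ExpressionBlock,
    labels: SampleLabels,
    test_block: ExpressionBlock,
):
    """Fit on the training block and predict hard labels for the test block.

    Features are canonically sorted before fitting so the result never
    depends on input feature order; train/test feature sets must match.
    """
    tr_set, te_set = set(train_block.feature_ids), set(test_block.feature_ids)
    if tr_set != te_set:
        missing = sorted(tr_set - te_set)[:5]
        extra = sorted(te_set - tr_set)[:5]
        raise ValueError(f"feature mismatch; missing from test: {missing}, extra: {extra}")
    order = sorted(train_block.feature_ids)
    tr = train_block.subset_features(order)
    te = test_block.subset_features(order)
    y = labels.y_for(tr.sample_ids)
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain both classes")
    model = fit_model(spec, tr.values.T, y)
    scores = model(te.values.T)
    predictions = (scores >= 0.5).astype(int)
    return predictions, model


# ---------------------------------------------------------------------------
# dataset preparation (leakage-safe)


@dataclass
class PreparedData:
    """Train/test feature matrices per feature type, with every statistic
    (normalization, filter, and later ranking/selection) fitted on the
    training samples only."""

    split: SplitAssignment
    train: dict[str, ExpressionBlock]
    test: dict[str, ExpressionBlock]
    raw_train: dict[str, ExpressionBlock]  # raw-scale retained features, for FC
    filter_pvalues: dict[str, dict[str, float]]
    norm_stats: dict


def prepare_dataset(
    mrna: ExpressionBlock,
    mirna: ExpressionBlock,
    labels: SampleLabels,
    split: SplitAssignment,
    norm_method: str = "log2_zscore",
    alpha: float = 0.05,
    ddof: int = 0,
) -> PreparedData:
    """Normalize each block on training statistics, t-test-filter on the
    training samples, and assemble mRNA / miRNA / combined matrices."""
    train_ids, test_ids = split.train_ids, split.test_ids
    train, test, raw_train, pvals, stats_map = {}, {}, {}, {}, {}
    norm_blocks_train, norm_blocks_test = [], []
    for raw in (mrna, mirna):
        norm, st = normalize_block(
            raw, norm_method, train_samples=train_ids, ddof=ddof, return_stats=True
        )
        filt = ttest_filter(raw, labels, alpha=alpha, samples=train_ids)
        kept = filt.retained
        norm_kept = norm.subset_features(kept)
        train[raw.block] = norm_kept.subset_samples(train_ids)
        test[raw.block] = norm_kept.subset_samples(test_ids)
        raw_train[raw.block] = raw.subset_features(kept).subset_samples(train_ids)
        pvals[raw.block] = filt.pvalues
        stats_map[raw.block] = st
        norm_blocks_train.append(train[raw.block])
        norm_blocks_test.append(test[raw.block])
    train["combined"] = combine_blocks(norm_blocks_train)
    test["combined"] = combine_blocks(norm_blocks_test)
    raw_comb = combine_blocks(list(raw_train.values()))
    raw_comb.block = "combined"
    raw_train["combined"] = raw_comb
    return PreparedData(split, train, test, raw_train, pvals, stats_map)


# ---------------------------------------------------------------------------
# feature selection within a prepared dataset


def select_for_cell(
    prepared: PreparedData,
    labels: SampleLabels,
    feature_type: str,
    selector: str,
    n: int | None,
    seed: int,
    bins: int = 10,
    k_neighbors: int = 10,
    stability_params: dict | None = None,
) -> list[str]:
    """Feature ids for one grid cell, computed from training data only."""
    train = prepared.train[feature_type]
    if selector == "all":
        return list(train.feature_ids)
    if selector == "shap":
        from .stability import run_stability_selection

        params = dict(stability_params or {})
        params.setdefault("seed", seed)
        result = run_stability_selection(train, labels.subset(train.sample_ids), **params)
        return sorted(result.selected)
    if n is None:
        raise ValueError(f"selector {selector!r} requires a top-n value")
    if selector == "fc":
        ranking = _rankers.rank_fold_change(prepared.raw_train[feature_type], labels.subset(train.sample_ids))
        ids = _rankers.top_n(ranking, min(n, len(ranking.feature_ids)))
        # FC ranks raw-scale retained features whose ids match the normalized block
        return ids
    if selector == "oner":
        ranking = _rankers.rank_oner(train, labels.subset(train.sample_ids), bins=bins)
    elif selector == "relieff":
        ranking = _rankers.rank_relieff(
            train, labels.subset(train.sample_ids), k_neighbors=k_neighbors, seed=seed
        )
    elif selector == "infogain":
        ranking = _rankers.rank_info_gain(train, labels.subset(train.sample_ids), bins=bins)
    elif selector == "gainratio":
        ranking = _rankers.rank_gain_ratio(train, labels.subset(train.sample_ids), bins=bins)
    else:
        raise ValueError(f"unknown selector {selector!r}")
    return _rankers.top_n(ranking, min(n, len(ranking.feature_ids)))


# ---------------------------------------------------------------------------
# benchmark runner


@dataclass
class BenchmarkConfig:
    feature_types: list[str] = field(default_factory=lambda: ["mRNA", "miRNA", "combined"])
    selectors: list[str] = field(default_factory=lambda: ["fc", "infogain", "all"])
    top_n: list[int] = field(default_factory=lambda: [30, 50, 100, 200, 300, 500])
    classifiers: list[ClassifierSpec] = field(
        default_factory=lambda: [ClassifierSpec("random_forest"), ClassifierSpec("logistic")]
    )
    seeds: list[int] = field(default_factory=lambda: [0])
    train_fraction: float = 0.8
    stratified_split: bool = True
    norm_method: str = "log2_zscore"
    alpha: float = 0.05
    bins: int = 10
    k_neighbors: int = 10
    stability_params: dict = field(default_factory=dict)
    results_path: str | None = None


RESULT_COLUMNS = [
    "feature_type",
    "selector",
    "n",
    "classifier",
    "seed",
    "n_features",
    "acc",
    "mcc",
    "f1",
    "status",
    "reason",
]


def _cell_key(feature_type, selector, n, classifier, seed) -> tuple:
    return (feature_type, selector, "" if n is None else str(n), classifier, str(seed))


def _load_done(path: str) -> tuple[list[dict], set[tuple]]:
    rows, done = [], set()
    if path and os.path.exists(path):
        df = pd.read_csv(path, sep="\t", comment="#")
        for rec in df.to_dict("records"):
            n = rec.get("n")
            n = None if (n is None or (isinstance(n, float) and np.isnan(n))) else int(n)
            rec["n"] = n
            rows.append(rec)
            done.add(_cell_key(rec["feature_type"], rec["selector"], n, rec["classifier"], rec["seed"]))
    return rows, done


def run_benchmark(
    mrna: ExpressionBlock,
    mirna: ExpressionBlock,
    labels: SampleLabels,
    config: BenchmarkConfig,
) -> pd.DataFrame:
    """Run the factorial grid; per-cell failures are caught and recorded,
    never silently dropped. Cells already present in ``results_path`` are
    skipped on rerun."""
    rows, done = _load_done(config.results_path) if config.results_path else ([], set())
    out_fh = None
    if config.results_path:
        new_file = not os.path.exists(config.results_path)
        out_fh = open(config.results_path, "a", encoding="utf-8")
        if new_file:
            out_fh.write(SCHEMA_HEADER + "\n")
            out_fh.write("\t".join(RESULT_COLUMNS) + "\n")

    prepared_by_seed: dict[int, PreparedData] = {}
    try:
        for seed in config.seeds:
            for feature_type in config.feature_types:
                for selector in config.selectors:
                    n_values = config.top_n if selector in _rankers.RANKERS else [None]
                    for n in n_values:
                        for spec in config.classifiers:
                            key = _cell_key(feature_type, selector, n, spec.name, seed)
                            if key in done:
                                continue
                            t0 = time.monotonic()
                            rec = _run_cell(
                                mrna, mirna, labels, config, prepared_by_seed,
                                feature_type, selector, n, spec, seed,
                            )
                            logger.info(
                                "cell %s: %s in %.2fs", key, rec["status"], time.monotonic() - t0
                            )
                            rows.append(rec)
                            done.add(key)
                            if out_fh:
                                out_fh.write(
                                    "\t".join(
                                        "" if rec[c] is None else str(rec[c])
                                        for c in RESULT_COLUMNS
                                    )
                                    + "\n"
                                )
                                out_fh.flush()
    finally:
        if out_fh:
            out_fh.close()
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


def _run_cell(mrna, mirna, labels, config, prepared_by_seed, feature_type, selector, n, spec, seed):
    rec = {
        "feature_type": feature_type,
        "selector": selector,
        "n": n,
        "classifier": spec.name,
        "seed": seed,
        "n_features": None,
        "acc": None,
        "mcc": None,
        "f1": None,
        "status": "ok",
        "reason": "",
    }
    try:
        if seed not in prepared_by_seed:
            split = split_train_test(
                labels, config.train_fraction, seed=seed, stratified=config.stratified_split
            )
            prepared_by_seed[seed] = prepare_dataset(
                mrna, mirna, labels, split, config.norm_method, config.alpha
            )
        prepared = prepared_by_seed[seed]
        feats = select_for_cell(
            prepared, labels, feature_type, selector, n, seed,
            bins=config.bins, k_neighbors=config.k_neighbors,
            stability_params=config.stability_params,
        )
        if not feats:
            raise ValueError("selector returned an empty feature set")
        train = prepared.train[feature_type].subset_features(feats)
        test = prepared.test[feature_type].subset_features(feats)
        cell_spec = ClassifierSpec(spec.name, dict(spec.params), spec.seed + seed)
        preds, _ = fit_predict(cell_spec, train, labels, test)
        m = metric_set(confusion(preds, labels.y_for(test.sample_ids)))
        rec.update(n_features=len(feats), acc=m.acc, mcc=m.mcc, f1=m.f1)
    except Exception as exc:  # per-cell failures are data, not crashes
        rec.update(status="failed", reason=f"{type(exc).__name__}: {exc}")
    return rec


def summarize(results: pd.DataFrame, group_by) -> pd.DataFrame:
    """Mean and median of each metric per group."""
    if results.empty:
        raise ValueError("no results to summarize")
    if isinstance(group_by, str):
        group_by = [group_by]
    unknown = [g for g in group_by if g not in results.columns]
    if unknown:
        raise ValueError(f"unknown grouping key(s): {unknown}")
    ok = results[results["status"] == "ok"]
    out = ok.groupby(group_by, dropna=False)[METRIC_COLUMNS].agg(["mean", "median"])
    out.columns = [f"{m}_{s}" for m, s in out.columns]
    return out.reset_index()
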