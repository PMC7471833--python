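"""Cross-fold Shapley stability selection.

The selection strategy: split the samples into K stratified folds; for
each fold, fit a classifier on the fold's training portion, compute the
Shapley value of every (training sample, feature) pair, and score each
feature by the sum of absolute Shapley values over the training samples.
Binarize each fold's scores by keeping the top-k features, sum the binary
indicators across folds into a per-feature fold count F_y, and select the
features with F_y strictly greater than the threshold (defaults: K = 10
folds, top 300 per fold, threshold 5 — i.e. flagged in at least 6 folds).

The held-out tenth of each fold is deliberately unused: importance is
computed on the training portion only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .io_prep import ExpressionBlock, SampleLabels, substream
from .shapley import ShapMatrix, shap_matrix

DEFAULT_FOLDS = 10
DEFAULT_TOPK = 300
DEFAULT_THRESHOLD = 5
DEFAULT_BACKGROUND_SIZE = 100


@dataclass
class FoldImportance:
    """Per-feature importance for one fold: the sum of absolute Shapley
    values over that fold's training samples."""

    fold: int
    feature_ids: list[str]
    importance: np.ndarray

    def __post_init__(self) -> None:
        self.importance = np.asarray(self.importance, dtype=float)
        if self.importance.shape != (len(self.feature_ids),):
            raise ValueError("importance must align with feature ids")
        if np.any(self.importance < 0):
            raise ValueError("summed absolute Shapley values cannot be negative")


@dataclass
class StabilityProfile:
    """K x Y fold-indicator matrix and the aggregated fold counts F_y."""

    feature_ids: list[str]
    indicators: np.ndarray  # (K, Y) binary
    topk: int
    threshold: int

    def __post_init__(self) -> None:
        self.indicators = np.asarray(self.indicators, dtype=int)
        if self.indicators.ndim != 2 or self.indicators.shape[1] != len(self.feature_ids):
            raise ValueError("indicator matrix must be folds x features")

    @property
    def n_folds(self) -> int:
        return self.indicators.shape[0]

    @property
    def fold_counts(self) -> np.ndarray:
        return self.indicators.sum(axis=0)

    def write_tsv(self, path) -> None:
        F = self.fold_counts
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(
                "feature_id\tF_y\t" + "\t".join(f"fold{k+1}" for k in range(self.n_folds)) + "\n"
            )
            for j, fid in enumerate(self.feature_ids):
                flags = "\t".join(str(int(v)) for v in self.indicators[:, j])
                fh.write(f"{fid}\t{int(F[j])}\t{flags}\n")


def fold_importance(shap: ShapMatrix, fold: int = 0) -> FoldImportance:
    """Column-wise sum of absolute Shapley values (no sign cancellation)."""
    if shap.values.size == 0:
        raise ValueError("empty ShapMatrix")
    return FoldImportance(fold, list(shap.feature_ids), np.abs(shap.values).sum(axis=0))


def binarize_topk(imp: FoldImportance, topk: int) -> np.ndarray:
    """Binary indicator keeping the top-k importances (ties broken by
    importance descending then feature id ascending); all features are
    kept when k exceeds the feature count."""
    if topk < 1:
        raise ValueError("topk must be >= 1")
    Y = len(imp.feature_ids)
    order = sorted(range(Y), key=lambda j: (-imp.importance[j], imp.feature_ids[j]))
    flag = np.zeros(Y, dtype=int)
    flag[order[: min(topk, Y)]] = 1
    return flag


def aggregate_folds(indicators: list[np.ndarray]) -> np.ndarray:
    """Element-wise sum of per-fold binary indicators into F_y."""
    if not indicators:
        raise ValueError("no fold indicators to aggregate")
    shapes = {np.asarray(ind).shape for ind in indicators}
    if len(shapes) != 1:
        raise ValueError(f"fold indicators have mismatched feature spaces: {sorted(shapes)}")
    return np.sum([np.asarray(ind, dtype=int) for ind in indicators], axis=0)


def select_features(F: np.ndarray, feature_ids: list[str], threshold: int = DEFAULT_THRESHOLD):
    """Features with F_y strictly greater than the threshold (a count of
    exactly ``threshold`` folds is NOT selected)."""
    F = np.asarray(F)
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    return {fid for fid, f in zip(feature_ids, F) if f > threshold}


@dataclass
class SelectionResult:
    selected: set[str]
    profile: StabilityProfile
    fold_importances: list[FoldImportance] = field(default_factory=list)
    fold_assignments: list[tuple[list[str], list[str]]] = field(default_factory=list)


def make_folds(
    labels: SampleLabels, n_folds: int, seed: int, stratified: bool = True
) -> list[tuple[list[str], list[str]]]:
    """Seeded (train_ids, heldout_ids) partition; stratified by default so
    every training portion contains both classes."""
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    ids = sorted(labels.sample_ids)
    y = labels.y_for(ids)
    rng = substream(seed, "folds")
    state = int(rng.integers(0, 2**32 - 1))
    if stratified:
        splitter = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=state)
        split_iter = splitter.split(np.zeros(len(ids)), y)
    else:
        from sklearn.model_selection import KFold

        split_iter = KFold(n_splits=n_folds, shuffle=True, random_state=state).split(
            np.zeros(len(ids))
        )
    folds = []
    for train_idx, test_idx in split_iter:
        train = [ids[i] for i in train_idx]
        if len(np.unique(y[train_idx])) < 2:
            raise ValueError(
                "a fold's training portion contains a single class; use stratified folds"
            )
        folds.append((train, [ids[i] for i in test_idx]))
    return folds


def run_stability_selection(
    block: ExpressionBlock,
    labels: SampleLabels,
    n_folds: int = DEFAULT_FOLDS,
    topk: int = DEFAULT_TOPK,
    threshold: int = DEFAULT_THRESHOLD,
    model_spec=None,
    seed: int = 0,
    background_size: int = DEFAULT_BACKGROUND_SIZE,
    shap_method: str = "auto",
    n_permutations: int = 20,
    stratified: bool = True,
) -> SelectionResult:
    """Full cross-fold stability selection on one (possibly combined) block.

    Per fold: fit ``model_spec`` (default: the built-in random forest) on
    the training portion, explain that same portion against a seeded
    background subsample of it, sum absolute Shapley values per feature,
    and flag the fold's top-``topk``. Features flagged in more than
    ``threshold`` folds are selected. Fully deterministic given ``seed``.
    """
    from .evalbench import ClassifierSpec, fit_model  # deferred: avoids import cycle

    if not 0 <= threshold <= n_folds:
        raise ValueError(f"threshold must be in [0, {n_folds}]")
    if model_spec is None:
        model_spec = ClassifierSpec("random_forest")
    folds = make_folds(labels, n_folds, seed, stratified=stratified)
    bg_rng = substream(seed, "background")

    indicators: list[np.ndarray] = []
    importances: list[FoldImportance] = []
    for k, (train_ids, _) in enumerate(folds):
        sub = block.subset_samples(train_ids)
        y = labels.y_for(train_ids)
        X = sub.values.T
        model = fit_model(model_spec, X, y, seed_offset=k)
        n_bg = min(background_size, X.shape[0])
        bg_idx = np.sort(bg_rng.choice(X.shape[0], size=n_bg, replace=False))
        shap = shap_matrix(
            model,
            X[bg_idx],
            X,
            feature_ids=sub.feature_ids,
            sample_ids=train_ids,
            method=shap_method,
            n_permutations=n_permutations,
            seed=seed + 7919 * k,
        )
        imp = fold_importance(shap, fold=k + 1)
        importances.append(imp)
        indicators.append(binarize_topk(imp, topk))
    F = aggregate_folds(indicators)
    selected = select_features(F, block.feature_ids, threshold)
    profile = StabilityProfile(list(block.feature_ids), np.vstack(indicators), topk, threshold)
    return SelectionResult(selected, profile, importances, folds)
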