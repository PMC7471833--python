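"""Five classical feature-ranking methods and top-n extraction.

Fold change is computed on raw-scale values (it is defined on expression
ratios); OneR, ReliefF, InfoGain and GainRatio expect normalized values so
distances and discretization are comparable across features.

Ties are always broken by (weight descending, feature_id ascending) —
reproducibility is preferred over fidelity to any particular toolkit's
internal ordering.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .io_prep import ExpressionBlock, SampleLabels, substream

FC_PSEUDOCOUNT_SCALE = 1e-6  # epsilon = scale x global mean expression


@dataclass
class FeatureRanking:
    """Ordered (feature_id, weight) pairs from one ranker.

    ``order_key`` records how entries were canonically sorted: by signed
    weight, or by absolute weight for direction-preserving methods (FC).
    """

    method: str
    feature_ids: list[str]
    weights: np.ndarray
    order_key: str = "weight"  # "weight" | "abs_weight"

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.feature_ids) != len(self.weights):
            raise ValueError("feature ids and weights must align")
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("ranking weights must be finite")

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.feature_ids, self.weights))


def _canonical_order(feature_ids, weights, key) -> tuple[list[str], np.ndarray]:
    w = np.abs(weights) if key == "abs_weight" else np.asarray(weights, dtype=float)
    order = sorted(range(len(feature_ids)), key=lambda i: (-w[i], feature_ids[i]))
    return [feature_ids[i] for i in order], np.asarray(weights, dtype=float)[order]


def _make_ranking(method, feature_ids, weights, key="weight") -> FeatureRanking:
    ids, w = _canonical_order(feature_ids, weights, key)
    return FeatureRanking(method, ids, w, key)


def _class_matrices(block: ExpressionBlock, labels: SampleLabels):
    y = labels.y_for(block.sample_ids)
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError("both classes must be present for ranking")
    return block.values, y


# ---------------------------------------------------------------------------
# fold change


def rank_fold_change(block: ExpressionBlock, labels: SampleLabels) -> FeatureRanking:
    """log2 fold change of class means, positive over negative group.

    A symmetric pseudocount (1e-6 of the global mean expression) guards
    all-zero features, which get weight 0.
    """
    vals, y = _class_matrices(block, labels)
    if np.any(vals < 0):
        raise ValueError("fold change requires raw-scale (nonnegative) values")
    eps = FC_PSEUDOCOUNT_SCALE * float(vals.mean()) if vals.size else 0.0
    eps = eps if eps > 0 else 1e-12
    mean_pos = vals[:, y == 1].mean(axis=1)
    mean_neg = vals[:, y == 0].mean(axis=1)
    weights = np.log2((mean_pos + eps) / (mean_neg + eps))
    return _make_ranking("fc", block.feature_ids, weights, key="abs_weight")


def top_n_fold_change(ranking: FeatureRanking, n: int) -> list[str]:
    """Top ceil(n/2) upregulated plus floor(n/2) downregulated features.

    A direction short of its quota is backfilled from the other direction
    with a warning.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    if n > len(ranking.feature_ids):
        raise ValueError(f"n={n} exceeds the {len(ranking.feature_ids)} ranked features")
    n_up = int(np.ceil(n / 2))
    n_down = n - n_up
    fid, w = ranking.feature_ids, ranking.weights
    up = sorted((i for i in range(len(fid)) if w[i] > 0), key=lambda i: (-w[i], fid[i]))
    down = sorted((i for i in range(len(fid)) if w[i] <= 0), key=lambda i: (w[i], fid[i]))
    take_up, take_down = up[:n_up], down[:n_down]
    short = n - len(take_up) - len(take_down)
    if short > 0:
        warnings.warn(
            f"a fold-change direction has fewer than {max(n_up, n_down)} features; "
            f"backfilling {short} from the other direction"
        )
        if len(take_up) < n_up:
            take_down = down[: n_down + short]
        else:
            take_up = up[: n_up + short]
    return [fid[i] for i in take_up + take_down]


# ---------------------------------------------------------------------------
# discretization shared by OneR / InfoGain / GainRatio


def discretize_equal_frequency(x: np.ndarray, bins: int = 10) -> np.ndarray:
    """Equal-frequency bin codes; collapses gracefully when there are
    fewer distinct values than bins (each distinct value is its own bin)."""
    if bins < 1:
        raise ValueError("bins must be >= 1")
    x = np.asarray(x, dtype=float)
    uniq = np.unique(x)
    if len(uniq) <= bins:
        return np.searchsorted(uniq, x)
    edges = np.unique(np.quantile(x, np.linspace(0, 1, bins + 1)[1:-1]))
    return np.searchsorted(edges, x, side="left")


# ---------------------------------------------------------------------------
# OneR


def rank_oner(block: ExpressionBlock, labels: SampleLabels, bins: int = 10) -> FeatureRanking:
    """One-rule weight per feature: discretize, predict each bin's majority
    class, weight = training accuracy (1 - error rate)."""
    vals, y = _class_matrices(block, labels)
    n = len(y)
    weights = np.empty(block.n_features)
    for i in range(block.n_features):
        codes = discretize_equal_frequency(vals[i], bins)
        correct = 0
        for b in np.unique(codes):
            in_bin = codes == b
            pos = int(y[in_bin].sum())
            correct += max(pos, int(in_bin.sum()) - pos)
        weights[i] = correct / n
    return _make_ranking("oner", block.feature_ids, weights)


# ---------------------------------------------------------------------------
# entropy-based rankers


def _entropy(counts: np.ndarray) -> float:
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    if total == 0:
        return 0.0
    p = counts[counts > 0] / total
    return float(-(p * np.log2(p)).sum())


def _info_gain_from_codes(codes: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Return (InfoGain in bits, H(V) in bits) for one discretized feature."""
    n = len(y)
    h_y = _entropy(np.bincount(y))
    h_cond = 0.0
    bin_counts = []
    for b in np.unique(codes):
        in_bin = codes == b
        nb = int(in_bin.sum())
        bin_counts.append(nb)
        h_cond += nb / n * _entropy(np.bincount(y[in_bin]))
    return h_y - h_cond, _entropy(np.array(bin_counts))


def rank_info_gain(block: ExpressionBlock, labels: SampleLabels, bins: int = 10) -> FeatureRanking:
    """Mutual information (bits) between the discretized feature and the label."""
    vals, y = _class_matrices(block, labels)
    weights = np.empty(block.n_features)
    for i in range(block.n_features):
        ig, _ = _info_gain_from_codes(discretize_equal_frequency(vals[i], bins), y)
        weights[i] = ig
    return _make_ranking("infogain", block.feature_ids, weights)


def rank_gain_ratio(block: ExpressionBlock, labels: SampleLabels, bins: int = 10) -> FeatureRanking:
    """InfoGain normalized by the entropy of the discretized feature;
    defined as 0 for constant features (H(V) = 0)."""
    vals, y = _class_matrices(block, labels)
    weights = np.empty(block.n_features)
    for i in range(block.n_features):
        ig, h_v = _info_gain_from_codes(discretize_equal_frequency(vals[i], bins), y)
        weights[i] = ig / h_v if h_v > 0 else 0.0
    return _make_ranking("gainratio", block.feature_ids, weights)


# ---------------------------------------------------------------------------
# ReliefF


def rank_relieff(
    block: ExpressionBlock,
    labels: SampleLabels,
    k_neighbors: int = 10,
    m_samples: int | None = None,
    seed: int = 0,
) -> FeatureRanking:
    """Classic ReliefF on normalized values.

    For each anchor, the weight of feature f gains the mean range-scaled
    difference to its k nearest other-class neighbors and loses the mean
    difference to its k nearest same-class neighbors:

        w_f += sum_miss diff(f)/(m k) - sum_hit diff(f)/(m k)

    Neighbor search is Euclidean over all features; diff is |a-b| scaled
    by the feature range (0 for constant features). Samples are sorted by
    id before anchor sampling so input order never changes the result;
    deterministic given ``seed``. ``m_samples=None`` uses every sample as
    an anchor.
    """
    order = sorted(range(block.n_samples), key=lambda i: block.sample_ids[i])
    sample_ids = [block.sample_ids[i] for i in order]
    vals = block.values[:, order]
    y = labels.y_for(sample_ids)
    n = len(y)
    counts = np.bincount(y, minlength=2)
    if counts.min() < k_neighbors + 1:
        raise ValueError(
            f"each class needs >= k_neighbors+1 samples; got {counts.tolist()} with k={k_neighbors}"
        )
    rng = substream(seed, "relieff")
    if m_samples is None or m_samples >= n:
        anchors = np.arange(n)
    else:
        anchors = np.sort(rng.choice(n, size=m_samples, replace=False))
    m = len(anchors)

    frange = vals.max(axis=1) - vals.min(axis=1)
    scale = np.where(frange > 0, frange, 1.0)
    X = vals.T  # samples x features
    D = cdist(X[anchors], X)
    weights = np.zeros(block.n_features)
    for a_pos, a in enumerate(anchors):
        d = D[a_pos].copy()
        d[a] = np.inf
        for cls in (0, 1):
            members = np.flatnonzero(y == cls)
            members = members[members != a]
            near = members[np.argsort(d[members], kind="stable")[:k_neighbors]]
            diffs = np.abs(vals[:, near] - vals[:, [a]]) / scale[:, None]
            diffs[frange == 0, :] = 0.0
            contrib = diffs.sum(axis=1) / (m * k_neighbors)
            weights += contrib if cls != y[a] else -contrib
    return _make_ranking("relieff", block.feature_ids, weights)


# ---------------------------------------------------------------------------
# top-n


RANKERS = {
    "fc": rank_fold_change,
    "oner": rank_oner,
    "relieff": rank_relieff,
    "infogain": rank_info_gain,
    "gainratio": rank_gain_ratio,
}


def top_n(ranking: FeatureRanking, n: int) -> list[str]:
    """First n feature ids in canonical order; fold-change rankings
    delegate to the directional top-n/2 rule."""
    if n > len(ranking.feature_ids):
        raise ValueError(f"n={n} exceeds the {len(ranking.feature_ids)} ranked features")
    if ranking.method == "fc":
        return top_n_fold_change(ranking, n)
    return ranking.feature_ids[:n]
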