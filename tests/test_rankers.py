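import math

import numpy as np
import pytest

from shapsel import rankers
from shapsel.io_prep import ExpressionBlock, SampleLabels
from shapsel.rankers import (
    FeatureRanking,
    discretize_equal_frequency,
    rank_fold_change,
    rank_gain_ratio,
    rank_info_gain,
    rank_oner,
    rank_relieff,
    top_n,
    top_n_fold_change,
)


def _block(values, tag="mRNA"):
    values = np.asarray(values, dtype=float)
    return ExpressionBlock(
        [f"f{i}" for i in range(values.shape[0])],
        [f"s{i}" for i in range(values.shape[1])],
        values,
        tag,
    )


def _labels(y):
    return SampleLabels([f"s{i}" for i in range(len(y))], np.asarray(y))


def _swap(labels):
    return SampleLabels(labels.sample_ids, 1 - labels.y)


class TestFoldChange:
    def test_ratio_arithmetic(self):
        b = _block([[8.0, 8.0, 2.0, 2.0]])
        r = rank_fold_change(b, _labels([1, 1, 0, 0]))
        assert r.weights[0] == pytest.approx(2.0, abs=1e-4)

    def test_identical_means_zero(self):
        b = _block([[3.0, 5.0, 3.0, 5.0]])
        r = rank_fold_change(b, _labels([1, 1, 0, 0]))
        assert r.weights[0] == pytest.approx(0.0, abs=1e-12)

    def test_antisymmetry(self):
        b = _block([[2.0, 2.0, 8.0, 8.0]])
        r = rank_fold_change(b, _labels([1, 1, 0, 0]))
        assert r.weights[0] == pytest.approx(-2.0, abs=1e-4)

    def test_all_zero_feature_weight_zero(self):
        b = _block([[0.0, 0.0, 0.0, 0.0], [1.0, 1.0, 2.0, 2.0]])
        r = rank_fold_change(b, _labels([1, 1, 0, 0]))
        assert r.as_dict()["f0"] == pytest.approx(0.0, abs=1e-12)

    def test_label_swap_negates(self):
        rng = np.random.default_rng(0)
        b = _block(rng.gamma(2.0, 2.0, size=(10, 12)))
        y = _labels([1, 1, 1, 1, 1, 1, 0, 0, 0, 0, 0, 0])
        w1, w2 = rank_fold_change(b, y).as_dict(), rank_fold_change(b, _swap(y)).as_dict()
        for f in w1:
            assert w1[f] == pytest.approx(-w2[f], abs=1e-9)


class TestTopNFoldChange:
    def _ranking(self, weights):
        return FeatureRanking("fc", [f"f{i}" for i in range(len(weights))],
                              np.asarray(weights, float), "abs_weight")

    def test_direct_selection(self):
        r = self._ranking([3.0, 2.0, 1.0, -1.0, -2.0])
        assert set(top_n_fold_change(r, 4)) == {"f0", "f1", "f3", "f4"}

    def test_n_zero_empty(self):
        assert top_n_fold_change(self._ranking([1.0, -1.0]), 0) == []

    def test_backfill_with_warning(self):
        r = self._ranking([4.0, 3.0, 2.0, 1.0])
        with pytest.warns(UserWarning, match="backfill"):
            out = top_n_fold_change(r, 4)
        assert set(out) == {"f0", "f1", "f2", "f3"}

    def test_odd_n_takes_extra_up(self):
        r = self._ranking([3.0, 2.0, 1.0, -1.0, -2.0])
        out = top_n_fold_change(r, 3)
        assert set(out) == {"f0", "f1", "f4"}  # ceil(3/2)=2 up, 1 down

    def test_n_exceeds_features_rejected(self):
        with pytest.raises(ValueError):
            top_n_fold_change(self._ranking([1.0]), 2)


class TestOneR:
    def test_perfect_binary_separator(self):
        b = _block([[0.0, 0.0, 1.0, 1.0]])
        r = rank_oner(b, _labels([0, 0, 1, 1]))
        assert r.weights[0] == 1.0

    def test_constant_feature_majority_rule(self):
        # single bin, 70% majority class -> weight 0.7
        b = _block([[5.0] * 10])
        r = rank_oner(b, _labels([1] * 7 + [0] * 3))
        assert r.weights[0] == pytest.approx(0.7)

    def test_independent_feature_near_half(self):
        # majority-class baseline ~0.5 for balanced classes, large n
        rng = np.random.default_rng(1)
        n = 2000
        b = _block(rng.normal(size=(1, n)))
        y = np.repeat([0, 1], n // 2)
        r = rank_oner(b, _labels(y), bins=10)
        assert 0.5 <= r.weights[0] < 0.56

    def test_label_swap_invariant(self):
        rng = np.random.default_rng(2)
        b = _block(rng.normal(size=(6, 20)))
        y = _labels(rng.integers(0, 2, 20) | np.array([1] + [0] * 19))
        np.testing.assert_allclose(
            sorted(rank_oner(b, y).weights), sorted(rank_oner(b, _swap(y)).weights)
        )


def _entropy_oracle(counts):
    """Independent brute-force entropy in bits."""
    total = sum(counts)
    return -sum(c / total * math.log2(c / total) for c in counts if c > 0) if total else 0.0


def _info_gain_oracle(table):
    """InfoGain/GainRatio from a bins x classes contingency table, by the
    textbook definitions evaluated with plain Python arithmetic."""
    n = sum(sum(row) for row in table)
    class_tot = [sum(row[c] for row in table) for c in range(2)]
    h_y = _entropy_oracle(class_tot)
    h_cond = sum(sum(row) / n * _entropy_oracle(row) for row in table if sum(row))
    h_v = _entropy_oracle([sum(row) for row in table])
    ig = h_y - h_cond
    return ig, (ig / h_v if h_v > 0 else 0.0)


def _realize(table):
    """Materialize a 2-bin table as a dataset (bin encoded as value 0/1)."""
    xs, ys = [], []
    for v, row in enumerate(table):
        for c, count in enumerate(row):
            xs += [float(v)] * count
            ys += [c] * count
    return _block([xs]), _labels(ys)


class TestEntropyRankers:
    def test_perfect_predictor_balanced(self):
        b, y = _realize([[4, 0], [0, 4]])
        assert rank_info_gain(b, y).weights[0] == pytest.approx(1.0)
        assert rank_gain_ratio(b, y).weights[0] == pytest.approx(1.0)

    def test_independent_feature_zero(self):
        # bin class-proportions equal to the marginal -> exactly 0
        b, y = _realize([[2, 2], [3, 3]])
        assert rank_info_gain(b, y).weights[0] == pytest.approx(0.0, abs=1e-12)

    def test_worked_two_bin_example(self):
        # bins (6 pos / 2 neg) and (2 pos / 6 neg): H(Y)=1, H(Y|V)=0.8113
        b, y = _realize([[2, 6], [6, 2]])
        expected = 1.0 - (-0.75 * math.log2(0.75) - 0.25 * math.log2(0.25))
        assert expected == pytest.approx(0.18872, abs=1e-4)  # hand arithmetic
        assert rank_info_gain(b, y).weights[0] == pytest.approx(expected, abs=1e-12)
        assert rank_gain_ratio(b, y).weights[0] == pytest.approx(expected, abs=1e-12)

    def test_constant_feature_gain_ratio_zero(self):
        b = _block([[2.0] * 6])
        y = _labels([0, 0, 0, 1, 1, 1])
        assert rank_gain_ratio(b, y).weights[0] == 0.0
        assert rank_info_gain(b, y).weights[0] == pytest.approx(0.0, abs=1e-12)

    def test_exhaustive_small_tables_match_oracle(self):
        # all 2-bin x 2-class tables with cells <= 4 (unit-scale version of
        # the acceptance check at cells <= 8)
        for a in range(5):
            for b_ in range(5):
                for c in range(5):
                    for d in range(5):
                        table = [[a, b_], [c, d]]
                        n = a + b_ + c + d
                        if n == 0 or a + b_ == 0 or c + d == 0:
                            continue
                        if a + c == 0 or b_ + d == 0:
                            continue  # both classes must be present
                        block, labels = _realize(table)
                        ig_o, gr_o = _info_gain_oracle(table)
                        assert rank_info_gain(block, labels).weights[0] == pytest.approx(
                            ig_o, abs=1e-12
                        )
                        assert rank_gain_ratio(block, labels).weights[0] == pytest.approx(
                            gr_o, abs=1e-12
                        )

    def test_info_gain_bounded_by_class_entropy(self):
        rng = np.random.default_rng(3)
        b = _block(rng.normal(size=(20, 30)))
        y = rng.integers(0, 2, 30)
        y[0], y[1] = 0, 1
        labels = _labels(y)
        h_y = _entropy_oracle(np.bincount(y).tolist())
        assert np.all(rank_info_gain(b, labels).weights <= h_y + 1e-12)

    def test_label_swap_invariant(self):
        rng = np.random.default_rng(4)
        b = _block(rng.normal(size=(8, 24)))
        y = _labels(np.repeat([0, 1], 12))
        for fn in (rank_info_gain, rank_gain_ratio):
            np.testing.assert_allclose(
                sorted(fn(b, y).weights), sorted(fn(b, _swap(y)).weights), atol=1e-12
            )


def _relieff_oracle(values, y, k, scale_guard=True):
    """Naive loop-based ReliefF with all samples as anchors (independent of
    the vectorized implementation)."""
    n_feat, n = values.shape
    frange = values.max(axis=1) - values.min(axis=1)
    w = np.zeros(n_feat)
    for a in range(n):
        dist = np.sqrt(((values - values[:, [a]]) ** 2).sum(axis=0))
        dist[a] = np.inf
        for cls in (0, 1):
            idx = [i for i in range(n) if y[i] == cls and i != a]
            idx.sort(key=lambda i: dist[i])
            for h in idx[:k]:
                for f in range(n_feat):
                    d = abs(values[f, h] - values[f, a]) / frange[f] if frange[f] > 0 else 0.0
                    w[f] += (d if cls != y[a] else -d) / (n * k)
    return w


class TestReliefF:
    def test_constant_feature_exactly_zero(self):
        rng = np.random.default_rng(5)
        vals = rng.normal(size=(3, 12))
        vals[1] = 7.0
        b = _block(vals)
        r = rank_relieff(b, _labels(np.repeat([0, 1], 6)), k_neighbors=2)
        assert r.as_dict()["f1"] == 0.0

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(6)
        vals = rng.normal(size=(4, 10))
        y = np.repeat([0, 1], 5)
        b = _block(vals)
        r = rank_relieff(b, _labels(y), k_neighbors=2)
        # oracle iterates samples in index order == canonical id order here
        expected = _relieff_oracle(vals, y, k=2)
        got = r.as_dict()
        for i in range(4):
            assert got[f"f{i}"] == pytest.approx(expected[i], abs=1e-12)

    def test_signal_feature_ranks_first(self):
        for seed in range(10):
            rng = np.random.default_rng(seed)
            n = 40
            y = np.repeat([0, 1], n // 2)
            vals = rng.normal(size=(6, n))
            vals[0] += 3.0 * y  # the only class-linked feature
            r = rank_relieff(_block(vals), _labels(y), k_neighbors=5, seed=seed)
            assert r.feature_ids[0] == "f0"

    def test_duplicating_samples_keeps_order(self):
        # brute-force check on a 6-sample toy: duplicate every sample and
        # scale k accordingly
        vals = np.array(
            [[0.0, 0.1, 0.2, 1.0, 1.1, 1.2],
             [0.3, 0.9, 0.1, 0.8, 0.2, 0.7],
             [5.0, 5.2, 5.1, 5.3, 5.0, 5.2]]
        )
        y = np.array([0, 0, 0, 1, 1, 1])
        b1 = _block(vals)
        order1 = rank_relieff(b1, _labels(y), k_neighbors=1).feature_ids
        dup_vals = np.repeat(vals, 2, axis=1)
        dup_y = np.repeat(y, 2)
        b2 = ExpressionBlock(b1.feature_ids, [f"s{i:02d}" for i in range(12)], dup_vals, "mRNA")
        order2 = rank_relieff(b2, SampleLabels(b2.sample_ids, dup_y), k_neighbors=3).feature_ids
        assert order1 == order2

    def test_sample_order_permutation_invariant(self):
        rng = np.random.default_rng(7)
        vals = rng.normal(size=(5, 14))
        y = np.array([0] * 7 + [1] * 7)
        b = _block(vals)
        r1 = rank_relieff(b, _labels(y), k_neighbors=3, seed=1)
        perm = rng.permutation(14)
        b2 = ExpressionBlock(b.feature_ids, [b.sample_ids[i] for i in perm], vals[:, perm], "mRNA")
        lab2 = SampleLabels(b2.sample_ids, y[perm])
        r2 = rank_relieff(b2, lab2, k_neighbors=3, seed=1)
        assert r1.feature_ids == r2.feature_ids
        np.testing.assert_allclose(r1.weights, r2.weights, atol=1e-12)

    def test_small_class_rejected(self):
        b = _block(np.ones((2, 4)))
        with pytest.raises(ValueError, match="k_neighbors"):
            rank_relieff(b, _labels([0, 0, 0, 1]), k_neighbors=2)


class TestTopNAndInvariants:
    def test_permutation_invariant_all_rankers(self, small_dataset):
        mrna, _, labels, _ = small_dataset
        from shapsel.io_prep import normalize_block

        norm = normalize_block(mrna)
        for name, fn in rankers.RANKERS.items():
            block = mrna if name == "fc" else norm
            kwargs = {"seed": 0} if name == "relieff" else {}
            r = fn(block, labels, **kwargs)
            assert sorted(r.feature_ids) == sorted(block.feature_ids)
            assert np.all(np.isfinite(r.weights))

    def test_top_n_full_and_single(self):
        r = FeatureRanking("infogain", ["a", "b", "c"], np.array([3.0, 2.0, 1.0]))
        assert top_n(r, 3) == ["a", "b", "c"]
        assert top_n(r, 1) == ["a"]

    def test_top_n_too_large_rejected(self):
        r = FeatureRanking("infogain", ["a"], np.array([1.0]))
        with pytest.raises(ValueError):
            top_n(r, 2)

    def test_tied_weights_lexicographic(self):
        ids = ["z", "m", "a", "q"]
        r = rankers._make_ranking("oner", ids, np.array([0.5, 0.5, 0.5, 0.9]))
        assert r.feature_ids == ["q", "a", "m", "z"]
        assert top_n(r, 2) == ["q", "a"]

    def test_discretize_collapses_few_values(self):
        codes = discretize_equal_frequency(np.array([1.0, 1.0, 2.0, 2.0]), bins=10)
        assert set(codes) == {0, 1}

    def test_discretize_equal_frequency_balance(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=1000)
        codes = discretize_equal_frequency(x, bins=10)
        counts = np.bincount(codes)
        assert len(counts) == 10
        assert counts.min() > 70 and counts.max() < 130
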