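"""Filter criteria against independent brute-force oracles and their
invariances."""

import math
from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from fnro import (
    FScoreSelector,
    InfoGainSelector,
    MRMRSelector,
    ReliefFSelector,
    anova_f,
    entropy,
    fscore_binary,
    information_gain,
    mrmr_rank,
    relieff_scores,
    score_genes,
    top_k,
)
from fnro.exceptions import DomainError
from fnro.filters import FilterScores, equal_frequency_bins, rank_by_score


# ---------------------------------------------------------------------------
# brute-force oracles (independent of the implementation path)
# ---------------------------------------------------------------------------

def bf_entropy(labels):
    n = len(labels)
    return -sum(
        (c / n) * math.log2(c / n) for c in Counter(labels).values()
    )


def bf_gain_from_codes(codes, labels):
    """Entropy reduction given an already-discretized feature."""
    n = len(labels)
    cond = 0.0
    for b in set(codes):
        sub = [l for c, l in zip(codes, labels) if c == b]
        cond += (len(sub) / n) * bf_entropy(sub)
    return bf_entropy(labels) - cond


def bf_fscore(feature, labels):
    pos = [x for x, l in zip(feature, labels) if l == 0]
    neg = [x for x, l in zip(feature, labels) if l == 1]
    mu = sum(feature) / len(feature)
    mp, mn = sum(pos) / len(pos), sum(neg) / len(neg)
    num = (mp - mu) ** 2 + (mn - mu) ** 2
    den = sum((x - mp) ** 2 for x in pos) / (len(pos) - 1) + sum(
        (x - mn) ** 2 for x in neg
    ) / (len(neg) - 1)
    return float("inf") if den == 0 and num > 0 else (0.0 if den == 0 else num / den)


def bf_anova(feature, labels):
    groups = [
        [x for x, l in zip(feature, labels) if l == c] for c in sorted(set(labels))
    ]
    n, m = len(feature), len(groups)
    grand = sum(feature) / n
    ssb = sum(len(g) * (sum(g) / len(g) - grand) ** 2 for g in groups)
    ssw = sum(sum((x - sum(g) / len(g)) ** 2 for x in g) for g in groups)
    msb, msw = ssb / (m - 1), ssw / (n - m)
    return float("inf") if msw == 0 and msb > 0 else (0.0 if msw == 0 else msb / msw)


def bf_mi(a, b):
    """Mutual information (nats) from the contingency table."""
    n = len(a)
    mi = 0.0
    for (va, vb), c in Counter(zip(a, b)).items():
        pa = sum(1 for x in a if x == va) / n
        pb = sum(1 for x in b if x == vb) / n
        pab = c / n
        mi += pab * math.log(pab / (pa * pb))
    return mi


def bf_mrmr_criteria(codes, labels, selected):
    """Criterion value of every unselected gene given an already-selected
    set, by direct evaluation of the difference form."""
    p = codes.shape[1]
    crits = {}
    for j in range(p):
        if j in selected:
            continue
        crit = bf_mi(list(codes[:, j]), list(labels))
        if selected:
            crit -= sum(
                bf_mi(list(codes[:, j]), list(codes[:, s])) for s in selected
            ) / len(selected)
        crits[j] = crit
    return crits


def bf_mrmr(codes, labels, k):
    """Exhaustive greedy evaluation of the difference criterion (first index
    wins ties)."""
    selected = []
    while len(selected) < k:
        crits = bf_mrmr_criteria(codes, labels, selected)
        selected.append(max(crits, key=lambda j: (crits[j], -j)))
    return selected


# ---------------------------------------------------------------------------
# worked examples
# ---------------------------------------------------------------------------

class TestEntropy:
    @pytest.mark.parametrize(
        "labels,expected",
        [([0, 0, 1, 1], 1.0), ([0, 1, 2, 3], 2.0), ([0, 0, 0], 0.0)],
    )
    def test_examples(self, labels, expected):
        assert entropy(labels) == pytest.approx(expected)

    def test_empty_rejected(self):
        with pytest.raises(DomainError):
            entropy([])


class TestInformationGain:
    def test_perfect_split_recovers_entropy(self):
        assert information_gain([1, 1, 9, 9], [0, 0, 1, 1], bins=2) == pytest.approx(1.0)

    def test_constant_feature_zero(self):
        assert information_gain([3, 3, 3, 3], [0, 0, 1, 1], bins=2) == 0.0

    def test_uninformative_split_zero(self):
        assert information_gain([1, 9, 1, 9], [0, 0, 1, 1], bins=2) == pytest.approx(0.0)

    def test_length_mismatch(self):
        with pytest.raises(DomainError):
            information_gain([1, 2], [0, 0, 1])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_bounded_by_label_entropy(self, seed):
        rng = np.random.default_rng(seed)
        feature = rng.standard_normal(12)
        labels = rng.integers(0, 3, 12)
        if len(np.unique(labels)) < 2:
            labels[0], labels[1] = 0, 1
        gain = information_gain(feature, labels, bins=4)
        assert 0.0 <= gain <= entropy(labels) + 1e-12


class TestFScore:
    def test_hand_worked_example(self):
        f = fscore_binary([1, 2, 3, -1, -2, -3], [0, 0, 0, 1, 1, 1])
        assert f == pytest.approx(4.0)

    def test_equal_means_zero(self):
        f = fscore_binary([1.0, 3.0, 1.0, 3.0], [0, 0, 1, 1])
        assert f == 0.0

    def test_zero_variance_sentinel(self):
        assert fscore_binary([2, 2, 5, 5], [0, 0, 1, 1]) == math.inf

    def test_multiclass_rejected(self):
        with pytest.raises(DomainError):
            fscore_binary([1, 2, 3], [0, 1, 2])

    def test_tiny_class_rejected(self):
        with pytest.raises(DomainError):
            fscore_binary([1, 2, 3], [0, 0, 1])


class TestAnovaF:
    def test_hand_worked_example(self):
        assert anova_f([1, 2, 3, 4], [0, 0, 1, 1]) == pytest.approx(8.0)

    def test_equal_group_means_zero(self):
        assert anova_f([1.0, 3.0, 1.0, 3.0], [0, 0, 1, 1]) == 0.0

    def test_zero_within_variance_sentinel(self):
        assert anova_f([0, 0, 1, 1], [0, 0, 1, 1]) == math.inf

    def test_no_within_df_rejected(self):
        with pytest.raises(DomainError):
            anova_f([1, 2], [0, 1])

    def test_matches_scipy_f_oneway(self):
        rng = np.random.default_rng(7)
        x = rng.standard_normal(15)
        y = np.array([0] * 5 + [1] * 5 + [2] * 5)
        expected = sps.f_oneway(x[y == 0], x[y == 1], x[y == 2]).statistic
        assert anova_f(x, y) == pytest.approx(expected, rel=1e-12)


@settings(max_examples=40, deadline=None, derandomize=True)
@given(
    st.integers(0, 10_000),
    st.floats(-50, 50),
    st.floats(0.01, 100),
)
def test_fscore_and_anova_shift_and_scale_invariant(seed, shift, scale):
    """Both statistics ignore additive shifts and multiplicative scaling."""
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(12)
    y = np.array([0] * 6 + [1] * 6)
    for fn in (fscore_binary, anova_f):
        base = fn(x, y)
        assert fn(x + shift, y) == pytest.approx(base, rel=1e-6, abs=1e-9)
        assert fn(x * scale, y) == pytest.approx(base, rel=1e-6, abs=1e-9)


def test_fscore_and_anova_induce_same_ranking_balanced_binary():
    """Both statistics are monotone in the between/within variance ratio."""
    rng = np.random.default_rng(3)
    for _ in range(20):
        X = rng.standard_normal((10, 20))
        y = np.array([0] * 5 + [1] * 5)
        f = np.array([fscore_binary(X[:, j], y) for j in range(20)])
        a = np.array([anova_f(X[:, j], y) for j in range(20)])
        np.testing.assert_array_equal(rank_by_score(f), rank_by_score(a))


class TestReliefF:
    def test_perfect_feature_gets_top_weight(self):
        rng = np.random.default_rng(0)
        y = np.array([0] * 10 + [1] * 10)
        X = np.column_stack([y.astype(float), rng.standard_normal(20),
                             rng.standard_normal(20)])
        w = relieff_scores(X, y, n_neighbors=3)
        assert w[0] > 0
        assert np.argmax(w) == 0

    def test_pure_noise_weight_near_zero(self):
        vals = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            y = np.array([0] * 15 + [1] * 15)
            X = rng.standard_normal((30, 3))
            w = relieff_scores(X, y, n_neighbors=5, n_iterations=200, rng=rng)
            vals.append(np.abs(w).max())
        assert np.mean(vals) < 0.1

    def test_duplicated_rows_preserve_ranking(self):
        rng = np.random.default_rng(4)
        y = np.array([0] * 5 + [1] * 5)
        X = np.column_stack([
            y + 0.1 * rng.standard_normal(10),     # strong
            y + 0.8 * rng.standard_normal(10),     # medium
            rng.standard_normal(10),               # noise
        ])
        w1 = relieff_scores(X, y, n_neighbors=2)
        Xd, yd = np.repeat(X, 2, axis=0), np.repeat(y, 2)
        w2 = relieff_scores(Xd, yd, n_neighbors=2)
        np.testing.assert_array_equal(np.argsort(-w1), np.argsort(-w2))

    def test_small_class_rejected_with_guidance(self):
        X = np.zeros((6, 2))
        y = np.array([0, 0, 0, 0, 1, 1])
        with pytest.raises(DomainError, match="n_neighbors"):
            relieff_scores(X, y, n_neighbors=3)

    def test_weights_bounded(self):
        rng = np.random.default_rng(9)
        X = rng.standard_normal((24, 8))
        y = rng.integers(0, 3, 24)
        y[:6] = [0, 0, 1, 1, 2, 2]
        w = relieff_scores(X, y, n_neighbors=1)
        assert np.all(w >= -1.0) and np.all(w <= 1.0)


class TestMRMR:
    def test_first_gene_is_mi_argmax(self):
        rng = np.random.default_rng(2)
        y = np.array([0] * 10 + [1] * 10)
        X = rng.standard_normal((20, 8))
        X[:, 5] += 3 * y  # clearly most relevant
        order = mrmr_rank(X, y, k=3, bins=4)
        assert order[0] == 5

    def test_exact_copy_penalized(self):
        """Gene A relevant, A' an exact copy, B moderately relevant and
        independent: order starts A then B."""
        rng = np.random.default_rng(8)
        n = 40
        y = np.array([0] * 20 + [1] * 20)
        a = y + 0.3 * rng.standard_normal(n)
        b = y + 1.2 * rng.standard_normal(n)
        X = np.column_stack([a, a.copy(), b])
        order = mrmr_rank(X, y, k=2, bins=5)
        assert list(order) == [0, 2]

    def test_k_equals_gene_count_is_permutation(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((12, 6))
        y = np.array([0, 1] * 6)
        order = mrmr_rank(X, y, k=6, bins=3)
        assert sorted(order) == list(range(6))

    def test_k_too_large_rejected(self):
        with pytest.raises(DomainError):
            mrmr_rank(np.zeros((4, 2)), [0, 0, 1, 1], k=3)

    def test_deterministic(self):
        rng = np.random.default_rng(5)
        X = rng.standard_normal((15, 10))
        y = np.array([0, 1, 2] * 5)
        o1 = mrmr_rank(X, y, k=5, bins=4)
        o2 = mrmr_rank(X, y, k=5, bins=4)
        np.testing.assert_array_equal(o1, o2)

    def test_matches_bruteforce_greedy(self):
        from fnro.filters import _discretize_matrix

        rng = np.random.default_rng(13)
        X = rng.standard_normal((10, 8))
        y = rng.integers(0, 2, 10)
        y[:2] = [0, 1]
        codes = _discretize_matrix(X, 4)
        expected = bf_mrmr(codes, y, k=4)
        got = mrmr_rank(X, y, k=4, bins=4)
        assert list(got) == expected


class TestRankingAndTopK:
    def test_ties_break_by_ascending_index(self):
        scores = FilterScores("fscore", np.array([1.0, 1.0]),
                              rank_by_score([1.0, 1.0]))
        assert list(top_k(scores, 1)) == [0]

    def test_top_k_examples(self):
        scores = FilterScores("fscore", np.array([3.0, 1.0, 2.0]),
                              rank_by_score([3.0, 1.0, 2.0]))
        assert set(top_k(scores, 2)) == {0, 2}
        assert set(top_k(scores, 3)) == {0, 1, 2}
        with pytest.raises(DomainError):
            top_k(scores, 4)

    def test_ranking_is_permutation(self):
        rng = np.random.default_rng(0)
        scores = rng.standard_normal(30)
        assert sorted(rank_by_score(scores)) == list(range(30))

    def test_inf_sentinel_sorts_first(self):
        r = rank_by_score([1.0, np.inf, 2.0])
        assert r[0] == 1


class TestSelectors:
    @pytest.mark.parametrize("cls,kwargs", [
        (FScoreSelector, {}),
        (InfoGainSelector, {"bins": 4}),
        (ReliefFSelector, {"n_neighbors": 3}),
        (MRMRSelector, {"bins": 4}),
    ])
    def test_transform_keeps_top_k(self, cls, kwargs, planted_ds):
        ds, truth = planted_ds
        sel = cls(k=10, **kwargs).fit(ds.values, ds.labels)
        assert sel.transform(ds.values).shape == (ds.n_samples, 10)
        assert sel.get_support().sum() == 10

    def test_fscore_selector_finds_planted_genes(self, planted_ds):
        ds, truth = planted_ds
        sel = FScoreSelector(k=10).fit(ds.values, ds.labels)
        chosen = set(np.flatnonzero(sel.get_support()))
        assert set(truth.informative_genes.tolist()) <= chosen

    def test_sklearn_clone_and_params(self):
        from sklearn.base import clone

        sel = InfoGainSelector(k=7, bins=6)
        cl = clone(sel)
        assert cl.get_params()["k"] == 7 and cl.get_params()["bins"] == 6


def test_equal_frequency_bins_splits_evenly():
    x = np.arange(100, dtype=float)
    codes = equal_frequency_bins(x, 4)
    _, counts = np.unique(codes, return_counts=True)
    assert counts.tolist() == [25, 25, 25, 25]


def test_score_genes_unknown_method(tiny_binary_ds):
    with pytest.raises(DomainError):
        score_genes(tiny_binary_ds, "chi2")
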