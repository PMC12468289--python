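"""Univariate and multivariate gene-relevance filters.

Four classifier-independent criteria rank genes before the wrapper search:

* **F-score** — ratio of between-class to within-class variance; the
  two-class form uses sample variances per class, the multiclass form is the
  one-way ANOVA F statistic.
* **Information Gain** — entropy reduction after equal-frequency
  discretization of the gene.
* **ReliefF** — multiclass nearest-hit/nearest-miss feature weighting.
* **mRMR** — greedy mutual-information selection maximizing class relevance
  minus mean redundancy with already-selected genes (difference form).

All tie-breaks are by ascending gene index so rankings are deterministic
across platforms.  Genes with zero within-class variance but distinct class
means receive a ``+inf`` sentinel score that sorts first: such a gene is a
perfect separator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.metrics import mutual_info_score
from sklearn.utils.validation import check_is_fitted, validate_data

from .dataset import ExpressionDataset
from .exceptions import DomainError

FILTER_METHODS = ("fscore", "infogain", "relieff", "mrmr")


@dataclass
class FilterScores:
    """Per-gene relevance scores and the derived deterministic ranking."""

    method: str
    scores: np.ndarray
    ranking: np.ndarray
    params: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# scalar criteria
# ---------------------------------------------------------------------------

def entropy(labels) -> float:
    """Shannon entropy of a class-code vector, in bits."""
    labels = np.asarray(labels)
    if labels.size == 0:
        raise DomainError("entropy of empty label vector is undefined")
    _, counts = np.unique(labels, return_counts=True)
    p = counts / labels.size
    return float(-(p * np.log2(p)).sum())


def equal_frequency_bins(feature, bins: int) -> np.ndarray:
    """Discretize a real vector into (up to) ``bins`` equal-frequency bins.

    Bin edges are sample quantiles; duplicate edges (heavy ties) are merged,
    so fewer than ``bins`` distinct codes may result.  A constant vector maps
    to a single bin.
    """
    feature = np.asarray(feature, dtype=float)
    if bins < 1:
        raise DomainError("bins must be >= 1")
    edges = np.unique(np.quantile(feature, np.linspace(0, 1, bins + 1)))
    if len(edges) <= 2:
        # 0 or 1 interior edge: at most 2 bins; handle constant explicitly
        if len(edges) == 1:
            return np.zeros(feature.size, dtype=int)
    # right-closed last bin: digitize against interior edges
    return np.digitize(feature, edges[1:-1], right=True)


def information_gain(feature, labels, bins: int = 10) -> float:
    """Entropy reduction of the class labels after partitioning samples by
    the equal-frequency-discretized feature.  Lies in [0, entropy(labels)]."""
    feature = np.asarray(feature, dtype=float)
    labels = np.asarray(labels)
    if feature.size != labels.size:
        raise DomainError("feature and labels must have the same length")
    codes = equal_frequency_bins(feature, bins)
    h = entropy(labels)
    cond = 0.0
    for b in np.unique(codes):
        mask = codes == b
        cond += (mask.sum() / labels.size) * entropy(labels[mask])
    gain = h - cond
    # clamp tiny negative round-off
    return float(max(gain, 0.0))


def fscore_binary(feature, labels) -> float:
    """Two-class F-score: squared deviations of the class means from the
    global mean over the sum of the per-class sample variances.

    Returns ``+inf`` when both within-class variances are zero but the class
    means differ (perfect separator); 0 when the means coincide.
    """
    feature = np.asarray(feature, dtype=float)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) != 2:
        raise DomainError(
            f"fscore_binary needs exactly 2 classes, got {len(classes)}; "
            "use anova_f for multiclass data"
        )
    pos = feature[labels == classes[0]]
    neg = feature[labels == classes[1]]
    if len(pos) < 2 or len(neg) < 2:
        raise DomainError("each class needs at least 2 samples")
    mu = feature.mean()
    num = (pos.mean() - mu) ** 2 + (neg.mean() - mu) ** 2
    den = pos.var(ddof=1) + neg.var(ddof=1)
    if den == 0.0:
        return float("inf") if num > 0 else 0.0
    return float(num / den)


def anova_f(feature, labels) -> float:
    """One-way ANOVA F statistic: between-group mean square over
    within-group mean square.  ``+inf`` sentinel on zero within-group
    variance with unequal group means."""
    feature = np.asarray(feature, dtype=float)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    m = len(classes)
    n = feature.size
    if m < 2:
        raise DomainError("anova_f needs at least 2 classes")
    if n <= m:
        raise DomainError("no within-group degrees of freedom (n <= m)")
    grand = feature.mean()
    ss_between = 0.0
    ss_within = 0.0
    for c in classes:
        g = feature[labels == c]
        ss_between += len(g) * (g.mean() - grand) ** 2
        ss_within += ((g - g.mean()) ** 2).sum()
    msb = ss_between / (m - 1)
    msw = ss_within / (n - m)
    if msw == 0.0:
        return float("inf") if msb > 0 else 0.0
    return float(msb / msw)


# ---------------------------------------------------------------------------
# matrix criteria
# ---------------------------------------------------------------------------

def relieff_scores(
    X,
    y,
    n_neighbors: int = 10,
    n_iterations: int | None = None,
    rng=None,
) -> np.ndarray:
    """Multiclass ReliefF feature weights.

    For each sampled instance the weight of each feature is decreased by the
    mean (range-scaled) difference to its ``n_neighbors`` nearest same-class
    neighbors (hits) and increased by the class-prior-weighted mean
    difference to the nearest neighbors of every other class (misses).
    Distances are Manhattan on range-scaled features.  With
    ``n_iterations=None`` every sample is visited once in order, making the
    pass fully deterministic.  Weights lie in [-1, 1].
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n, p = X.shape
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() < n_neighbors + 1:
        raise DomainError(
            f"smallest class has {counts.min()} samples; ReliefF with "
            f"n_neighbors={n_neighbors} needs every class to have at least "
            f"{n_neighbors + 1} — lower n_neighbors"
        )
    priors = dict(zip(classes, counts / n))
    rng_f = X.max(axis=0) - X.min(axis=0)
    rng_f[rng_f == 0.0] = 1.0  # constant features contribute 0 everywhere
    Xs = X / rng_f

    if n_iterations is None:
        picks = np.arange(n)
    else:
        if rng is None:
            rng = np.random.default_rng()
        picks = rng.integers(0, n, size=n_iterations)
    m = len(picks)

    w = np.zeros(p)
    for i in picks:
        dists = np.abs(Xs - Xs[i]).sum(axis=1)
        order = np.argsort(dists, kind="stable")
        diffs = np.abs(Xs - Xs[i])  # already range-scaled, in [0, 1]
        yi = y[i]
        hits = [j for j in order if j != i and y[j] == yi][:n_neighbors]
        w -= diffs[hits].mean(axis=0) / m
        for c in classes:
            if c == yi:
                continue
            misses = [j for j in order if y[j] == c][:n_neighbors]
            scale = priors[c] / (1.0 - priors[yi])
            w += scale * diffs[misses].mean(axis=0) / m
    return w


def _discretize_matrix(X, bins: int) -> np.ndarray:
    return np.column_stack(
        [equal_frequency_bins(X[:, j], bins) for j in range(X.shape[1])]
    )


def mrmr_rank(X, y, k: int, bins: int = 10) -> np.ndarray:
    """Greedy minimum-redundancy maximum-relevance selection order.

    The first gene maximizes MI(gene, class); each subsequent gene maximizes
    MI(gene, class) minus the mean MI with the already-selected genes
    (difference form).  MI is estimated on equal-frequency-discretized
    values.  Ties break by ascending gene index.  Returns the selection
    order (length ``k``).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n, p = X.shape
    if k > p:
        raise DomainError(f"k={k} exceeds gene count {p}")
    codes = _discretize_matrix(X, bins)
    relevance = np.array(
        [mutual_info_score(codes[:, j], y) for j in range(p)]
    )
    selected: list[int] = []
    remaining = np.ones(p, dtype=bool)
    redundancy_sum = np.zeros(p)
    for _ in range(k):
        if selected:
            crit = relevance - redundancy_sum / len(selected)
        else:
            crit = relevance.copy()
        crit[~remaining] = -np.inf
        best = int(np.argmax(crit))  # argmax takes the lowest index on ties
        selected.append(best)
        remaining[best] = False
        if remaining.any():
            for j in np.flatnonzero(remaining):
                redundancy_sum[j] += mutual_info_score(
                    codes[:, j], codes[:, best]
                )
    return np.array(selected, dtype=int)


# ---------------------------------------------------------------------------
# ranking helpers
# ---------------------------------------------------------------------------

def rank_by_score(scores) -> np.ndarray:
    """Gene indices sorted by decreasing score, ties by ascending index."""
    scores = np.asarray(scores, dtype=float)
    return np.lexsort((np.arange(scores.size), -scores))


def top_k(scores: FilterScores, k: int) -> np.ndarray:
    """The first ``k`` entries of the deterministic ranking, as a sorted
    gene index array."""
    if k > scores.ranking.size:
        raise DomainError(f"k={k} exceeds gene count {scores.ranking.size}")
    return np.sort(scores.ranking[:k])


def score_genes(
    ds: ExpressionDataset,
    method: str,
    bins: int = 10,
    relieff_neighbors: int = 10,
    relieff_iterations: int | None = None,
    mrmr_k: int | None = None,
) -> FilterScores:
    """Score every gene of a dataset with one filter method.

    For ``fscore`` the two-class form is used on binary data and the ANOVA F
    statistic on multiclass data.  For ``mrmr`` the score of a gene is
    ``n_genes - selection_rank`` so that the induced ranking equals the
    greedy selection order.
    """
    X, y = ds.values, ds.labels
    p = ds.n_genes
    if method == "fscore":
        fn = fscore_binary if ds.n_classes == 2 else anova_f
        scores = np.array([fn(X[:, j], y) for j in range(p)])
        params = {}
    elif method == "infogain":
        scores = np.array(
            [information_gain(X[:, j], y, bins=bins) for j in range(p)]
        )
        params = {"bins": bins}
    elif method == "relieff":
        scores = relieff_scores(
            X, y, n_neighbors=relieff_neighbors, n_iterations=relieff_iterations
        )
        params = {"n_neighbors": relieff_neighbors}
    elif method == "mrmr":
        order = mrmr_rank(X, y, k=mrmr_k or p, bins=bins)
        scores = np.full(p, -np.inf)
        scores[order] = np.arange(len(order), 0, -1, dtype=float)
        params = {"bins": bins}
    else:
        raise DomainError(
            f"unknown filter method {method!r}; choose from {FILTER_METHODS}"
        )
    return FilterScores(
        method=method, scores=scores, ranking=rank_by_score(scores), params=params
    )


def export_scores(scores: FilterScores, gene_ids, scores_path, ranking_path=None):
    """Write scores (gene_id, score) and optionally the ranking as CSV."""
    pd.DataFrame(
        {"gene_id": gene_ids, "score": scores.scores}
    ).to_csv(scores_path, index=False)
    if ranking_path is not None:
        pd.DataFrame(
            {
                "rank": np.arange(1, scores.ranking.size + 1),
                "gene_index": scores.ranking,
                "gene_id": [gene_ids[j] for j in scores.ranking],
            }
        ).to_csv(ranking_path, index=False)


# ---------------------------------------------------------------------------
# sklearn-style selectors
# ---------------------------------------------------------------------------

class _BaseFilterSelector(SelectorMixin, BaseEstimator):
    """Shared fit/transform machinery for the filter selectors.

    Subclasses implement ``_score(X, y)`` returning one relevance score per
    gene; ``fit`` derives the deterministic ranking and the top-``k``
    support mask.
    """

    def __init__(self, k=500):
        self.k = k

    def _score(self, X, y):  # pragma: no cover - abstract
        raise NotImplementedError

    def fit(self, X, y):
        X, y = validate_data(self, X, y)
        if self.k < 1 or self.k > X.shape[1]:
            raise DomainError(
                f"k={self.k} out of range for {X.shape[1]} genes"
            )
        self.scores_ = np.asarray(self._score(X, y), dtype=float)
        self.ranking_ = rank_by_score(self.scores_)
        return self

    def _get_support_mask(self):
        check_is_fitted(self, "ranking_")
        mask = np.zeros(self.ranking_.size, dtype=bool)
        mask[self.ranking_[: self.k]] = True
        return mask


class FScoreSelector(_BaseFilterSelector):
    """Select the top-k genes by F-score (ANOVA F for multiclass labels)."""

    def _score(self, X, y):
        fn = fscore_binary if len(np.unique(y)) == 2 else anova_f
        return [fn(X[:, j], y) for j in range(X.shape[1])]


class InfoGainSelector(_BaseFilterSelector):
    """Select the top-k genes by Information Gain on equal-frequency bins."""

    def __init__(self, k=500, bins=10):
        super().__init__(k=k)
        self.bins = bins

    def _score(self, X, y):
        return [
            information_gain(X[:, j], y, bins=self.bins)
            for j in range(X.shape[1])
        ]


class ReliefFSelector(_BaseFilterSelector):
    """Select the top-k genes by multiclass ReliefF weights."""

    def __init__(self, k=500, n_neighbors=10, n_iterations=None, random_state=None):
        super().__init__(k=k)
        self.n_neighbors = n_neighbors
        self.n_iterations = n_iterations
        self.random_state = random_state

    def _score(self, X, y):
        rng = np.random.default_rng(self.random_state)
        return relieff_scores(
            X,
            y,
            n_neighbors=self.n_neighbors,
            n_iterations=self.n_iterations,
            rng=rng,
        )


class MRMRSelector(_BaseFilterSelector):
    """Select k genes by greedy mRMR; ``scores_`` encode the selection order."""

    def __init__(self, k=500, bins=10):
        super().__init__(k=k)
        self.bins = bins

    def _score(self, X, y):
        order = mrmr_rank(X, y, k=self.k, bins=self.bins)
        p = X.shape[1]
        scores = np.zeros(p)
        scores[order] = np.arange(p, p - len(order), -1, dtype=float)
        return scores


FILTER_SELECTORS = {
    "fscore": FScoreSelector,
    "infogain": InfoGainSelector,
    "relieff": ReliefFSelector,
    "mrmr": MRMRSelector,
}
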