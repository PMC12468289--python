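"""Gene-subset fitness: linear-SVM accuracy under leave-one-out (or
stratified k-fold) cross-validation.

The classifier is a linear-kernel SVM with C = 1 by default, trained on the
globally normalized data restricted to the candidate gene subset.  LOOCV
holds out each sample once; pooled held-out predictions yield accuracy and
support-weighted precision/recall/F1.  Because the optimizer re-visits
duplicate subsets constantly, :func:`cached_fitness` memoizes results keyed
by the sorted gene-index tuple.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import precision_recall_fscore_support
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .dataset import ExpressionDataset
from .exceptions import ConfigError, DomainError


@dataclass
class FitnessConfig:
    """Classifier and cross-validation settings (linear kernel is fixed)."""

    C: float = 1.0
    cv: str = "loocv"  # or "kfold"
    folds: int = 5
    kfold_seed: int = 0
    cache_enabled: bool = True
    average: str = "weighted"  # or "macro"

    def __post_init__(self):
        if self.C <= 0:
            raise ConfigError("C must be positive")
        if self.cv not in ("loocv", "kfold"):
            raise ConfigError("cv must be 'loocv' or 'kfold'")
        if self.cv == "kfold" and self.folds < 2:
            raise ConfigError("folds must be >= 2")


@dataclass
class EvaluationResult:
    """Pooled held-out classification metrics for one gene subset."""

    accuracy: float
    precision: float
    recall: float
    f1: float
    per_sample_predictions: np.ndarray = field(repr=False, default=None)


def _check_subset(ds: ExpressionDataset, genes) -> np.ndarray:
    genes = np.asarray(list(genes), dtype=int)
    if genes.size == 0:
        raise DomainError("gene subset must be nonempty")
    if genes.min() < 0 or genes.max() >= ds.n_genes:
        raise DomainError("gene index out of range")
    _, counts = np.unique(ds.labels, return_counts=True)
    if counts.min() < 2:
        raise DomainError(
            "every class needs >= 2 samples for held-out evaluation"
        )
    return genes


def _metrics(y_true, y_pred, average: str) -> EvaluationResult:
    acc = float(np.mean(y_true == y_pred))
    prec, rec, f1, _ = precision_recall_fscore_support(
        y_true, y_pred, average=average, zero_division=0
    )
    return EvaluationResult(
        accuracy=acc,
        precision=float(prec),
        recall=float(rec),
        f1=float(f1),
        per_sample_predictions=np.asarray(y_pred),
    )


def loocv_accuracy(
    ds: ExpressionDataset, genes, cfg: FitnessConfig | None = None
) -> EvaluationResult:
    """Leave-one-out cross-validated metrics of a linear SVM on a subset.

    Each sample is held out once; the SVM is trained on the remaining
    samples restricted to ``genes`` and predicts the held-out sample.
    """
    cfg = cfg or FitnessConfig()
    genes = _check_subset(ds, genes)
    X = ds.values[:, genes]
    y = ds.labels
    n = len(y)
    preds = np.empty(n, dtype=int)
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        mask[i] = False
        clf = SVC(kernel="linear", C=cfg.C)
        clf.fit(X[mask], y[mask])
        preds[i] = clf.predict(X[i : i + 1])[0]
        mask[i] = True
    return _metrics(y, preds, cfg.average)


def kfold_accuracy(
    ds: ExpressionDataset, genes, cfg: FitnessConfig | None = None
) -> EvaluationResult:
    """Stratified k-fold cross-validated metrics (seeded shuffling).

    With ``folds`` equal to the sample count the split degenerates to
    leave-one-out (stratification is impossible on singleton folds).
    """
    cfg = cfg or FitnessConfig(cv="kfold")
    genes = _check_subset(ds, genes)
    n = ds.n_samples
    if cfg.folds == n:
        loo_cfg = FitnessConfig(C=cfg.C, cv="loocv", average=cfg.average)
        return loocv_accuracy(ds, genes, loo_cfg)
    _, counts = np.unique(ds.labels, return_counts=True)
    if cfg.folds > counts.min():
        raise DomainError(
            f"folds={cfg.folds} exceeds smallest class size {counts.min()}"
        )
    X = ds.values[:, genes]
    y = ds.labels
    preds = np.empty(n, dtype=int)
    skf = StratifiedKFold(
        n_splits=cfg.folds, shuffle=True, random_state=cfg.kfold_seed
    )
    for train_idx, test_idx in skf.split(X, y):
        clf = SVC(kernel="linear", C=cfg.C)
        clf.fit(X[train_idx], y[train_idx])
        preds[test_idx] = clf.predict(X[test_idx])
    return _metrics(y, preds, cfg.average)


def evaluate_subset(
    ds: ExpressionDataset, genes, cfg: FitnessConfig | None = None
) -> EvaluationResult:
    """Dispatch to LOOCV or k-fold according to ``cfg.cv``."""
    cfg = cfg or FitnessConfig()
    if cfg.cv == "kfold":
        return kfold_accuracy(ds, genes, cfg)
    return loocv_accuracy(ds, genes, cfg)


class CachedFitness:
    """Memoizing gene-subset fitness callable.

    Results are keyed by the sorted gene-index tuple, so ``{1, 2}`` and
    ``{2, 1}`` share one cache entry.  Calling the object returns the
    accuracy; :meth:`result` returns the full :class:`EvaluationResult`.
    Hit/miss counters support auditing the optimizer's duplicate rate.
    """

    def __init__(self, ds: ExpressionDataset, cfg: FitnessConfig | None = None):
        self.ds = ds
        self.cfg = cfg or FitnessConfig()
        self._cache: dict[tuple, EvaluationResult] = {}
        self.hits = 0
        self.misses = 0

    def result(self, genes) -> EvaluationResult:
        key = tuple(sorted(int(g) for g in genes))
        if self.cfg.cache_enabled and key in self._cache:
            self.hits += 1
            return self._cache[key]
        self.misses += 1
        res = evaluate_subset(self.ds, key, self.cfg)
        if self.cfg.cache_enabled:
            self._cache[key] = res
        return res

    def __call__(self, genes) -> float:
        return self.result(genes).accuracy


def cached_fitness(
    ds: ExpressionDataset, cfg: FitnessConfig | None = None
) -> CachedFitness:
    """Build a memoized subset-to-accuracy callable for the optimizer."""
    return CachedFitness(ds, cfg)
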