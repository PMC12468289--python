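"""The hybrid gene selector: filter pre-ranking + NRO wrapper search.

:class:`NROGeneSelector` is a scikit-learn transformer.  ``fit`` first
reduces the gene space with one of the four filter criteria (top
``pool_size`` genes) and then runs the NRO metaheuristic over the pool,
scoring every candidate subset by linear-SVM cross-validated accuracy.
``transform`` keeps the selected genes.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.utils.validation import check_is_fitted, validate_data

from .dataset import ExpressionDataset
from .exceptions import DomainError
from .filters import FILTER_METHODS, score_genes, top_k
from .fitness import CachedFitness, FitnessConfig
from .nro import NROConfig, run_nro


class NROGeneSelector(SelectorMixin, BaseEstimator):
    """Select a fixed-size gene subset by filter + NRO wrapper search.

    Parameters
    ----------
    n_genes : int
        Subset size k decoded from every NRO position.
    filter_method : {"fscore", "infogain", "relieff", "mrmr"}
        Pre-ranking criterion; "fscore" falls back to the ANOVA F statistic
        on multiclass labels.
    pool_size : int
        Number of top-ranked genes forming the NRO search space (the
        full-scale protocol uses 500).
    population_size, max_generations, patience, p_beta, levy_alpha,
    levy_beta, similarity_tol :
        NRO search parameters; see :class:`fnro.nro.NROConfig`.
    C : float
        SVM regularization.
    cv : {"loocv", "kfold"}, folds : int
        Fitness cross-validation protocol.
    random_state : int or None
        Seed for all randomness in the search.

    Attributes
    ----------
    filter_scores_ : ndarray
        Per-gene filter scores on the full input.
    pool_idx_ : ndarray
        Indices of the filtered gene pool (sorted).
    selected_idx_ : ndarray
        Indices of the selected genes (sorted), length ``n_genes``.
    support_ : ndarray of bool
        Mask over the input genes.
    best_score_ : float
        Cross-validated accuracy of the selected subset.
    trace_ : NROTrace
        Per-generation best fitness, evaluation count, early-stop flag.
    """

    def __init__(
        self,
        n_genes=5,
        filter_method="fscore",
        pool_size=50,
        population_size=30,
        max_generations=15,
        patience=5,
        p_beta=0.5,
        levy_alpha=0.01,
        levy_beta=1.5,
        similarity_tol=1e-10,
        bins=10,
        relieff_neighbors=10,
        C=1.0,
        cv="loocv",
        folds=5,
        random_state=None,
    ):
        self.n_genes = n_genes
        self.filter_method = filter_method
        self.pool_size = pool_size
        self.population_size = population_size
        self.max_generations = max_generations
        self.patience = patience
        self.p_beta = p_beta
        self.levy_alpha = levy_alpha
        self.levy_beta = levy_beta
        self.similarity_tol = similarity_tol
        self.bins = bins
        self.relieff_neighbors = relieff_neighbors
        self.C = C
        self.cv = cv
        self.folds = folds
        self.random_state = random_state

    def fit(self, X, y):
        X, y = validate_data(self, X, y)
        if self.filter_method not in FILTER_METHODS:
            raise DomainError(
                f"unknown filter method {self.filter_method!r}"
            )
        pool_size = min(self.pool_size, X.shape[1])
        if self.n_genes > pool_size:
            raise DomainError(
                f"n_genes={self.n_genes} exceeds pool size {pool_size}"
            )
        classes, codes = np.unique(y, return_inverse=True)
        ds = ExpressionDataset(
            values=X,
            gene_ids=[f"g{j}" for j in range(X.shape[1])],
            labels=codes,
            class_names=[str(c) for c in classes],
        )
        scores = score_genes(
            ds,
            self.filter_method,
            bins=self.bins,
            relieff_neighbors=self.relieff_neighbors,
            mrmr_k=pool_size if self.filter_method == "mrmr" else None,
        )
        self.filter_scores_ = scores.scores
        self.pool_idx_ = top_k(scores, pool_size)

        fit_cfg = FitnessConfig(C=self.C, cv=self.cv, folds=self.folds)
        fitness = CachedFitness(ds, fit_cfg)
        pool = self.pool_idx_

        def pool_fitness(subset):
            return fitness(pool[list(subset)])

        nro_cfg = NROConfig(
            population_size=self.population_size,
            max_generations=self.max_generations,
            patience=self.patience,
            p_beta=self.p_beta,
            levy_alpha=self.levy_alpha,
            levy_exponent=self.levy_beta,
            similarity_tol=self.similarity_tol,
            seed=self.random_state,
        )
        best, trace = run_nro(pool_fitness, d=pool_size, k=self.n_genes, cfg=nro_cfg)
        self.selected_idx_ = np.sort(pool[list(best.decoded)])
        self.best_score_ = best.fitness
        self.best_result_ = fitness.result(self.selected_idx_)
        self.trace_ = trace
        self.cache_stats_ = {"hits": fitness.hits, "misses": fitness.misses}
        self.support_ = np.zeros(X.shape[1], dtype=bool)
        self.support_[self.selected_idx_] = True
        return self

    def _get_support_mask(self):
        check_is_fitted(self, "support_")
        return self.support_
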