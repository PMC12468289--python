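"""Full protocol orchestration: filter sweep, subset-size sweep with repeated
stochastic runs, and aggregation into best/average/worst summaries.

The protocol mirrors the two-stage benchmark: first every filter method is
evaluated at several pool sizes by plain top-s LOOCV accuracy and the best
(method, size) pair is kept; then, over the winning pool, NRO runs
``repeats`` times at every subset size k, and the run-level accuracies are
aggregated into best/average/worst with a 95% normal-approximation
confidence interval on the mean.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataset import ExpressionDataset
from .exceptions import ConfigError, DomainError
from .filters import FILTER_METHODS, score_genes, top_k
from .fitness import CachedFitness, FitnessConfig
from .nro import NROConfig, run_nro

DEFAULT_FILTER_SIZES = (50, 100, 200, 300, 400, 500)


@dataclass
class SweepConfig:
    """Subset-size sweep settings (full-scale defaults: k = 2..25, 30
    repeats per k)."""

    filter_sizes: tuple = DEFAULT_FILTER_SIZES
    subset_sizes: tuple = tuple(range(2, 26))
    repeats: int = 30
    base_seed: int = 0
    stop_at_perfect: bool = True

    def __post_init__(self):
        if self.repeats < 1:
            raise ConfigError("repeats must be >= 1")
        if len(self.subset_sizes) == 0:
            raise ConfigError("subset_sizes must be nonempty")


@dataclass
class RunSummary:
    """Aggregate of the repeated runs at one subset size."""

    subset_size: int
    best_accuracy: float
    average_accuracy: float
    worst_accuracy: float
    precision: float
    recall: float
    f1: float
    ci_low: float
    ci_high: float
    best_genes: list = field(default_factory=list)
    seeds: list = field(default_factory=list)


def aggregate_ci(accuracies, method: str = "normal") -> tuple[float, float, float]:
    """Mean and 95% confidence interval of run accuracies.

    Normal approximation: mean +/- 1.96 * s / sqrt(n) with the sample
    standard deviation (n-1 divisor).  ``method="t"`` substitutes the
    Student-t quantile.  A single value yields a zero-width interval.
    """
    acc = np.asarray(list(accuracies), dtype=float)
    if acc.size == 0:
        raise DomainError("cannot aggregate an empty accuracy list")
    mean = float(acc.mean())
    if acc.size == 1:
        return mean, mean, mean
    s = float(acc.std(ddof=1))
    if method == "t":
        from scipy import stats

        q = float(stats.t.ppf(0.975, acc.size - 1))
    else:
        q = 1.96
    half = q * s / math.sqrt(acc.size)
    return mean, mean - half, mean + half


def evaluate_filters(
    ds: ExpressionDataset,
    methods=FILTER_METHODS,
    filter_sizes=DEFAULT_FILTER_SIZES,
    fitness_cfg: FitnessConfig | None = None,
    **filter_kwargs,
):
    """LOOCV accuracy of every (filter method, pool size) pair, no NRO.

    Returns ``(best_pair, grid)`` where ``grid[(method, size)]`` is the
    accuracy of the top-``size`` genes and ``best_pair`` is the argmax —
    ties broken by smaller size, then by the method order given.
    """
    fitness_cfg = fitness_cfg or FitnessConfig()
    for s in filter_sizes:
        if s > ds.n_genes:
            raise DomainError(f"filter size {s} exceeds gene count {ds.n_genes}")
    fitness = CachedFitness(ds, fitness_cfg)
    grid: dict[tuple, float] = {}
    for method in methods:
        scores = score_genes(ds, method, **filter_kwargs)
        for s in filter_sizes:
            grid[(method, s)] = fitness(top_k(scores, s))
    best_pair = max(
        grid,
        key=lambda pair: (
            grid[pair],
            -pair[1],
            -list(methods).index(pair[0]),
        ),
    )
    return best_pair, grid


def run_fnro_sweep(
    ds: ExpressionDataset,
    pool,
    sweep: SweepConfig,
    nro_cfg: NROConfig | None = None,
    fitness_cfg: FitnessConfig | None = None,
) -> list[RunSummary]:
    """Repeated NRO runs over the gene pool at every subset size.

    For each k the search runs ``sweep.repeats`` times with seeds
    ``base_seed .. base_seed + repeats - 1``; the run-level best accuracies
    are aggregated, and precision/recall/F1 are recomputed on the best run's
    subset.  With ``stop_at_perfect`` the sweep stops enlarging k once a
    best accuracy of 1.0 is reached.
    """
    pool = np.asarray(list(pool), dtype=int)
    nro_cfg = nro_cfg or NROConfig()
    fitness_cfg = fitness_cfg or FitnessConfig()
    if pool.size < max(sweep.subset_sizes):
        raise DomainError(
            f"pool size {pool.size} smaller than max subset size "
            f"{max(sweep.subset_sizes)}"
        )
    fitness = CachedFitness(ds, fitness_cfg)

    def pool_fitness(subset):
        return fitness(pool[list(subset)])

    summaries: list[RunSummary] = []
    for k in sweep.subset_sizes:
        accs, subsets, seeds = [], [], []
        for r in range(sweep.repeats):
            seed = sweep.base_seed + r
            cfg = dataclasses.replace(nro_cfg, seed=seed)
            best, _ = run_nro(pool_fitness, d=pool.size, k=k, cfg=cfg)
            accs.append(best.fitness)
            subsets.append(np.sort(pool[list(best.decoded)]))
            seeds.append(seed)
        mean, lo, hi = aggregate_ci(accs)
        best_run = int(np.argmax(accs))
        best_subset = subsets[best_run]
        best_eval = fitness.result(best_subset)
        summaries.append(
            RunSummary(
                subset_size=k,
                best_accuracy=float(np.max(accs)),
                average_accuracy=mean,
                worst_accuracy=float(np.min(accs)),
                precision=best_eval.precision,
                recall=best_eval.recall,
                f1=best_eval.f1,
                ci_low=lo,
                ci_high=hi,
                best_genes=[ds.gene_ids[j] for j in best_subset],
                seeds=seeds,
            )
        )
        if sweep.stop_at_perfect and summaries[-1].best_accuracy >= 1.0:
            break
    return summaries


def summaries_to_frame(summaries) -> pd.DataFrame:
    """Tabular rendering with accuracies as two-decimal percentages."""
    if not summaries:
        raise DomainError("no summaries to render")
    rows = []
    for s in summaries:
        rows.append(
            {
                "subset_size": s.subset_size,
                "best": f"{100 * s.best_accuracy:.2f}%",
                "average": f"{100 * s.average_accuracy:.2f}%",
                "worst": f"{100 * s.worst_accuracy:.2f}%",
                "precision": f"{100 * s.precision:.2f}%",
                "recall": f"{100 * s.recall:.2f}%",
                "f1": f"{100 * s.f1:.2f}%",
                "ci_95": f"[{100 * s.ci_low:.2f}%, {100 * s.ci_high:.2f}%]",
                "best_genes": ";".join(s.best_genes),
            }
        )
    return pd.DataFrame(rows)


def render_report(summaries, format: str, path) -> None:
    """Write the sweep summaries as ``csv`` (percent-formatted) or ``json``
    (raw values; round-trips via :func:`load_summaries`)."""
    if not summaries:
        raise DomainError("no summaries to render")
    if format == "csv":
        summaries_to_frame(summaries).to_csv(path, index=False)
    elif format == "json":
        with open(path, "w") as fh:
            json.dump([dataclasses.asdict(s) for s in summaries], fh, indent=2)
    else:
        raise ConfigError(f"unknown report format {format!r}")


def load_summaries(path) -> list[RunSummary]:
    """Read back a JSON report written by :func:`render_report`."""
    with open(path) as fh:
        records = json.load(fh)
    return [RunSummary(**r) for r in records]
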