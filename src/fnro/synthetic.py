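"""Synthetic microarray-like data with planted ground truth.

Generates a samples x genes Gaussian expression matrix in which a small set
of informative genes carries class-dependent mean shifts while all other
genes are class-independent noise.  Class means sit on a ladder
(0, delta, 2*delta, ...) with ``delta = effect_size * noise_sd``, so any two
classes are separated on every informative gene.  The planted index set is
returned alongside the dataset and serves as the recovery oracle for the
whole pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dataset import ExpressionDataset
from .exceptions import ConfigError


@dataclass
class SyntheticSpec:
    """Generator settings emulating small-n / large-p microarray structure
    (tens of samples, thousands of genes, 2-4 classes)."""

    n_samples: int = 60
    n_genes: int = 2000
    n_informative: int = 10
    n_classes: int = 2
    effect_size: float = 2.0  # class-mean shift in noise-sd units
    noise_sd: float = 1.0
    missing_rate: float = 0.0
    class_proportions: tuple | None = None  # uniform when None
    seed: int | None = None

    def __post_init__(self):
        if self.n_informative > self.n_genes:
            raise ConfigError("n_informative exceeds n_genes")
        if self.n_classes < 2:
            raise ConfigError("need at least 2 classes")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ConfigError("missing_rate must lie in [0, 1)")
        if self.noise_sd <= 0:
            raise ConfigError("noise_sd must be positive")
        if self.class_proportions is not None:
            props = np.asarray(self.class_proportions, dtype=float)
            if len(props) != self.n_classes or props.min() <= 0:
                raise ConfigError("class_proportions must be positive, one per class")


@dataclass
class SyntheticTruth:
    """Planted informative-gene indices and their per-class means."""

    informative_genes: np.ndarray  # sorted indices
    class_means: np.ndarray  # (n_classes, n_informative)


def _class_counts(spec: SyntheticSpec) -> np.ndarray:
    if spec.class_proportions is None:
        props = np.full(spec.n_classes, 1.0 / spec.n_classes)
    else:
        props = np.asarray(spec.class_proportions, dtype=float)
        props = props / props.sum()
    counts = np.floor(props * spec.n_samples).astype(int)
    # distribute the rounding remainder to the largest fractional parts
    frac = props * spec.n_samples - counts
    for j in np.argsort(-frac)[: spec.n_samples - counts.sum()]:
        counts[j] += 1
    if counts.min() < 2:
        raise ConfigError(
            f"every class needs >= 2 samples; got counts {counts.tolist()}"
        )
    return counts


def make_dataset(spec: SyntheticSpec) -> tuple[ExpressionDataset, SyntheticTruth]:
    """Generate one dataset plus its ground truth, reproducible from
    ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    counts = _class_counts(spec)
    labels = np.repeat(np.arange(spec.n_classes), counts)
    rng.shuffle(labels)

    values = rng.normal(0.0, spec.noise_sd, size=(spec.n_samples, spec.n_genes))
    informative = np.sort(
        rng.choice(spec.n_genes, size=spec.n_informative, replace=False)
    )
    delta = spec.effect_size * spec.noise_sd
    class_means = np.outer(np.arange(spec.n_classes), np.ones(spec.n_informative)) * delta
    values[:, informative] += labels[:, None] * delta

    if spec.missing_rate > 0:
        miss = rng.random(values.shape) < spec.missing_rate
        # never blank out an entire gene column (mean imputation needs a mean)
        full_cols = miss.all(axis=0)
        if full_cols.any():
            miss[0, full_cols] = False
        values[miss] = np.nan

    width = len(str(spec.n_genes))
    ds = ExpressionDataset(
        values=values,
        gene_ids=[f"G{j:0{width}d}" for j in range(spec.n_genes)],
        labels=labels,
        class_names=[f"class_{c}" for c in range(spec.n_classes)],
        meta={"source": "synthetic", "spec": spec.__dict__.copy()},
    )
    truth = SyntheticTruth(informative_genes=informative, class_means=class_means)
    return ds, truth


def recovery_score(selected, truth: SyntheticTruth) -> float:
    """Fraction of planted informative genes present in ``selected``."""
    planted = set(int(j) for j in truth.informative_genes)
    return len(planted & set(int(j) for j in selected)) / len(planted)
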