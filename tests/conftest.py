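import numpy as np
import pytest

from fnro import ExpressionDataset, SyntheticSpec, make_dataset, preprocess


@pytest.fixture
def tiny_binary_ds():
    """4 samples x 3 genes, two classes; gene 0 separates perfectly."""
    values = np.array(
        [
            [0.0, 5.0, 1.0],
            [0.2, 4.0, 9.0],
            [1.0, 6.0, 1.0],
            [0.8, 5.0, 9.0],
        ]
    )
    return ExpressionDataset(
        values=values,
        gene_ids=["g0", "g1", "g2"],
        labels=np.array([0, 0, 1, 1]),
        class_names=["a", "b"],
    )


@pytest.fixture
def separable_clumps_ds():
    """Two well-separated 1-D clumps plus a noise gene; 20 samples."""
    rng = np.random.default_rng(0)
    n = 10
    gene0 = np.concatenate([-5 + 0.1 * rng.standard_normal(n),
                            5 + 0.1 * rng.standard_normal(n)])
    noise = rng.standard_normal(2 * n)
    return ExpressionDataset(
        values=np.column_stack([gene0, noise]),
        gene_ids=["sep", "noise"],
        labels=np.array([0] * n + [1] * n),
        class_names=["neg", "pos"],
    )


@pytest.fixture(scope="session")
def planted_ds():
    """Preprocessed synthetic dataset with 5 planted genes among 200."""
    spec = SyntheticSpec(
        n_samples=60, n_genes=200, n_informative=5, n_classes=2,
        effect_size=2.0, seed=42,
    )
    ds, truth = make_dataset(spec)
    return preprocess(ds), truth
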