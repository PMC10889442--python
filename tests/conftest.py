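import numpy as np
import pytest

from geneximb import (
    ExpressionDataset,
    SyntheticSpec,
    generate,
    make_benchmark_fixtures,
)


@pytest.fixture(scope="session")
def benchmark_fixtures():
    """Synthetic datasets matching the four public benchmark schemas (500 -> 120 genes for speed)."""
    return make_benchmark_fixtures(n_genes=120, n_informative=20, effect_size=3.0, seed=0)


@pytest.fixture(scope="session")
def imbalanced_binary():
    """52:9 binary dataset, 200 genes, 10 informative at 3 sd — the canonical
    imbalance shape used across the oversampling and selection tests."""
    spec = SyntheticSpec(
        n_classes=2,
        samples_per_class={"maj": 52, "min": 9},
        n_genes=200,
        n_informative=10,
        effect_size=3.0,
        seed=7,
    )
    return generate(spec)


@pytest.fixture
def tiny_dataset():
    """4 samples x 3 genes, labels A,A,B,B — hand-checkable."""
    return ExpressionDataset(
        matrix=np.array([[2.0, 1.0, 0.0], [4.0, 1.0, 5.0], [6.0, 2.0, 1.0], [3.0, 9.0, 2.0]]),
        gene_ids=["g1", "g2", "g3"],
        sample_ids=["s1", "s2", "s3", "s4"],
        labels=np.array(["A", "A", "B", "B"], dtype=object),
    )
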