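"""Synthetic imbalanced microarray-like datasets with known informative genes.

The generator emulates the structure of public leukemia/colon expression
benchmarks: a handful of classes with strongly unequal sample counts
(minority:majority ratios down to 9:52), thousands of nonnegative intensity
columns of which only a small subset carries class signal.

Generative model: an informative gene in class ``c`` (classes indexed in the
order given) is drawn from ``Normal(base_intensity + c * effect_size * noise_sd,
noise_sd)``; every non-informative gene is drawn from
``Normal(base_intensity, noise_sd)`` regardless of class. Intensities are
clamped at zero. This is the simplest structure under which filter-selection
recovery of the informative set is provable; a log-normal variant is available
for more realistic skewed intensities.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, NamedTuple

import numpy as np

from .expression_data import ExpressionDataset

__all__ = ["SyntheticSpec", "generate", "BenchmarkFixture", "make_benchmark_fixtures"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Conditions for one synthetic dataset.

    ``effect_size`` is the between-class mean shift of informative genes in
    units of ``noise_sd``. Identical spec + seed yields a bit-identical dataset.
    """

    n_classes: int
    samples_per_class: Mapping[str, int]
    n_genes: int
    n_informative: int
    effect_size: float = 3.0
    noise_sd: float = 1.0
    base_intensity: float = 8.0
    log_normal: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if len(self.samples_per_class) != self.n_classes:
            raise ValueError("samples_per_class must have one entry per class")
        if any(c < 1 for c in self.samples_per_class.values()):
            raise ValueError("every samples_per_class count must be >= 1")
        if not (0 <= self.n_informative <= self.n_genes):
            raise ValueError("need 0 <= n_informative <= n_genes")
        if self.noise_sd <= 0 or self.base_intensity <= 0:
            raise ValueError("noise_sd and base_intensity must be positive")

    @classmethod
    def from_json(cls, text: str) -> "SyntheticSpec":
        return cls(**json.loads(text))


def generate(spec: SyntheticSpec) -> tuple[ExpressionDataset, list[str]]:
    """Draw one dataset from the spec; returns (dataset, informative gene ids).

    Gene ids are ``G0001..``; informative columns are placed at seeded random
    positions so selection methods cannot exploit column order.
    """
    rng = np.random.default_rng(spec.seed)
    classes = list(spec.samples_per_class)
    counts = [spec.samples_per_class[c] for c in classes]
    n = sum(counts)
    width = max(4, len(str(spec.n_genes)))
    gene_ids = [f"G{j + 1:0{width}d}" for j in range(spec.n_genes)]

    info_cols = np.sort(rng.choice(spec.n_genes, size=spec.n_informative, replace=False))
    matrix = rng.normal(spec.base_intensity, spec.noise_sd, size=(n, spec.n_genes))

    labels = np.empty(n, dtype=object)
    row = 0
    for c_idx, (cls, cnt) in enumerate(zip(classes, counts)):
        labels[row : row + cnt] = cls
        shift = c_idx * spec.effect_size * spec.noise_sd
        if shift and spec.n_informative:
            matrix[row : row + cnt, info_cols] += shift
        row += cnt

    if spec.log_normal:
        matrix = np.exp(matrix / spec.base_intensity * np.log(spec.base_intensity))
    np.clip(matrix, 0.0, None, out=matrix)

    data = ExpressionDataset(
        matrix=matrix,
        gene_ids=gene_ids,
        sample_ids=[f"s{i + 1:04d}" for i in range(n)],
        labels=labels,
    )
    return data, [gene_ids[j] for j in info_cols]


class BenchmarkFixture(NamedTuple):
    """A generated dataset plus its ground truth and fixed holdout indices."""

    dataset: ExpressionDataset
    informative_genes: list[str]
    train_indices: list[int]


# (class -> (train, total)) schemas of four published expression benchmarks:
# a 5-class leukemia microarray panel (64 samples), a 7-class lymphoblastic
# leukemia subtype set (327), the binary ALL/AML leukemia set (72), and the
# colon tumor/normal set (62).
_FIXTURE_SCHEMAS: dict[str, dict[str, tuple[int, int]]] = {
    "cumida": {
        "AML": (21, 26),
        "Bone_Marrow": (8, 10),
        "Bone_Marrow_CD34": (6, 8),
        "PB": (8, 10),
        "PBSC_CD34": (8, 10),
    },
    "subtype": {
        "BCR-ABL": (9, 15),
        "E2A-PBX1": (18, 27),
        "Hyperdiploid>50": (42, 64),
        "MLL": (14, 20),
        "T-ALL": (28, 43),
        "TEL-AML1": (52, 79),
        "Others": (52, 79),
    },
    "allaml": {"ALL": (27, 47), "AML": (11, 25)},
    "colon": {"Tumor": (28, 40), "Normal": (15, 22)},
}


def make_benchmark_fixtures(
    n_genes: int = 500,
    n_informative: int = 25,
    effect_size: float = 3.0,
    seed: int = 0,
) -> dict[str, BenchmarkFixture]:
    """Four synthetic datasets matching the class counts and holdout splits of
    the public benchmarks (gene counts reduced for speed; pass ``n_genes`` for
    full-scale shape)."""
    fixtures: dict[str, BenchmarkFixture] = {}
    for i, (name, schema) in enumerate(_FIXTURE_SCHEMAS.items()):
        spec = SyntheticSpec(
            n_classes=len(schema),
            samples_per_class={c: total for c, (tr, total) in schema.items()},
            n_genes=n_genes,
            n_informative=n_informative,
            effect_size=effect_size,
            seed=seed + i,
        )
        data, truth = generate(spec)
        # samples are generated grouped by class; the first `train` of each
        # class form the fixed training split, mirroring the published tables
        train_idx: list[int] = []
        row = 0
        for cls, (tr, total) in schema.items():
            train_idx.extend(range(row, row + tr))
            row += total
        fixtures[name] = BenchmarkFixture(data, truth, train_idx)
    return fixtures
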