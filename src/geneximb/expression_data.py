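"""Labeled gene-expression matrices: loading, validation, normalization, splitting.

The central container is :class:`ExpressionDataset`, a samples x genes matrix of
real-valued microarray intensities with gene ids, sample ids and one categorical
class label per sample. Files are read from delimited text (genes as columns,
one label column) or WEKA-dialect ARFF.

Min-max normalization rescales each gene to [0, 1] using per-gene extrema,
x' = (x - x_min) / (x_max - x_min). The extrema may be fitted on training data
only (the default, which prevents test-set leakage) or on a full dataset.
Values outside the fitted range map linearly outside [0, 1]; they are not
clipped. A constant gene (x_max == x_min) maps to 0, keeping it inert.
"""

from __future__ import annotations

import re
import warnings
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionDataset",
    "ClassDistribution",
    "NormalizationModel",
    "load_dataset",
    "save_dataset",
    "fit_normalizer",
    "apply_normalizer",
    "class_distribution",
    "fixed_holdout_split",
]


@dataclass
class ExpressionDataset:
    """A validated samples x genes expression matrix with class labels.

    Parameters
    ----------
    matrix
        Real intensities, shape ``(n_samples, n_genes)``. Samples are rows,
        genes are columns, everywhere in this package.
    gene_ids, sample_ids
        Ordered unique identifiers for columns / rows.
    labels
        One categorical class per sample.
    """

    matrix: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.labels = np.asarray(self.labels, dtype=object)
        if self.matrix.ndim != 2:
            raise ValueError("matrix must be 2-D (samples x genes)")
        n, p = self.matrix.shape
        if len(self.sample_ids) != n or len(self.labels) != n:
            raise ValueError(
                f"row count {n} must equal len(sample_ids)={len(self.sample_ids)} "
                f"and len(labels)={len(self.labels)}"
            )
        if len(self.gene_ids) != p:
            raise ValueError(f"column count {p} != len(gene_ids)={len(self.gene_ids)}")
        for name, ids in (("gene", self.gene_ids), ("sample", self.sample_ids)):
            dup = _first_duplicate(ids)
            if dup is not None:
                raise ValueError(f"duplicate {name} id: {dup!r}")
        if np.isnan(self.matrix).any():
            i, j = np.argwhere(np.isnan(self.matrix))[0]
            raise ValueError(
                f"missing value at sample {self.sample_ids[i]!r}, gene {self.gene_ids[j]!r}"
            )

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_genes(self) -> int:
        return self.matrix.shape[1]

    @property
    def classes(self) -> list:
        return sorted(set(self.labels.tolist()))

    def subset_samples(self, indices: Sequence[int]) -> "ExpressionDataset":
        idx = np.asarray(indices, dtype=int)
        return ExpressionDataset(
            matrix=self.matrix[idx].copy(),
            gene_ids=list(self.gene_ids),
            sample_ids=[self.sample_ids[i] for i in idx],
            labels=self.labels[idx].copy(),
        )

    def subset_genes(self, gene_ids: Sequence[str]) -> "ExpressionDataset":
        pos = {g: j for j, g in enumerate(self.gene_ids)}
        missing = [g for g in gene_ids if g not in pos]
        if missing:
            raise KeyError(f"unknown gene ids: {missing[:5]}")
        cols = [pos[g] for g in gene_ids]
        return ExpressionDataset(
            matrix=self.matrix[:, cols].copy(),
            gene_ids=list(gene_ids),
            sample_ids=list(self.sample_ids),
            labels=self.labels.copy(),
        )

    def to_frame(self, label_column: str = "class") -> pd.DataFrame:
        df = pd.DataFrame(self.matrix, index=self.sample_ids, columns=self.gene_ids)
        df[label_column] = self.labels
        return df


@dataclass(frozen=True)
class ClassDistribution:
    """Per-class sample counts with the majority and minority class singled out.

    Ties in the counts are broken by class-name order, so the attributes are
    deterministic for any labeling.
    """

    counts: Mapping[str, int]
    majority_class: str
    minority_class: str

    @property
    def majority_count(self) -> int:
        return self.counts[self.majority_class]

    @property
    def minority_count(self) -> int:
        return self.counts[self.minority_class]


@dataclass
class NormalizationModel:
    """Fitted per-gene min/max for Eq.-style min-max rescaling."""

    gene_ids: list[str]
    mins: np.ndarray
    maxs: np.ndarray
    fitted_on: str = "train-only"  # or "full"
    n_fit_samples: int = 0

    def __post_init__(self) -> None:
        self.mins = np.asarray(self.mins, dtype=float)
        self.maxs = np.asarray(self.maxs, dtype=float)
        if np.any(self.maxs < self.mins):
            raise ValueError("per-gene max must be >= min")


def _first_duplicate(ids: Iterable) -> object | None:
    seen: set = set()
    for x in ids:
        if x in seen:
            return x
        seen.add(x)
    return None


def load_dataset(
    path: str | Path,
    format: str | None = None,
    label_column: str = "class",
    transpose: bool = False,
) -> ExpressionDataset:
    """Load a labeled expression matrix from CSV/TSV or ARFF.

    CSV/TSV files carry a header row of gene ids plus one label column and an
    optional first index column of sample ids. With ``transpose=True`` a
    genes-as-rows file is flipped before validation (label row required).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = {".csv": "csv", ".tsv": "tsv", ".arff": "arff"}.get(path.suffix.lower(), "csv")
    if format == "arff":
        return _load_arff(path, label_column)
    sep = "\t" if format == "tsv" else ","
    df = pd.read_csv(path, sep=sep, index_col=0)
    if transpose:
        df = df.T
    if label_column not in df.columns:
        raise ValueError(f"label column {label_column!r} not found in {path.name}")
    labels = df[label_column].astype(str).to_numpy(dtype=object)
    expr = df.drop(columns=[label_column])
    for col in expr.columns:
        if not pd.api.types.is_numeric_dtype(expr[col]):
            bad = expr[col][pd.to_numeric(expr[col], errors="coerce").isna()]
            row = bad.index[0] if len(bad) else "?"
            raise ValueError(f"non-numeric value in gene column {col!r} (sample {row!r})")
    return ExpressionDataset(
        matrix=expr.to_numpy(dtype=float),
        gene_ids=[str(c) for c in expr.columns],
        sample_ids=[str(i) for i in expr.index],
        labels=labels,
    )


def save_dataset(
    data: ExpressionDataset,
    path: str | Path,
    format: str | None = None,
    label_column: str = "class",
) -> Path:
    """Write a dataset to CSV/TSV or ARFF so that :func:`load_dataset` round-trips it."""
    path = Path(path)
    if format is None:
        format = {".csv": "csv", ".tsv": "tsv", ".arff": "arff"}.get(path.suffix.lower(), "csv")
    if format == "arff":
        _save_arff(data, path, label_column)
        return path
    sep = "\t" if format == "tsv" else ","
    data.to_frame(label_column).to_csv(path, sep=sep, index_label="sample_id")
    return path


# -- ARFF (WEKA dialect): numeric gene attributes + one nominal class attribute.
# No installed package provides ARFF I/O, so the small subset needed here is
# implemented directly.

_ARFF_ATTR = re.compile(r"@attribute\s+(?:'([^']*)'|(\S+))\s+(.*)", re.IGNORECASE)


def _load_arff(path: Path, label_column: str) -> ExpressionDataset:
    attr_names: list[str] = []
    attr_kinds: list[str] = []  # "numeric" | "nominal"
    rows: list[list[str]] = []
    in_data = False
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("%"):
                continue
            if in_data:
                rows.append([tok.strip().strip("'") for tok in line.split(",")])
                continue
            low = line.lower()
            if low.startswith("@relation"):
                continue
            if low.startswith("@attribute"):
                m = _ARFF_ATTR.match(line)
                if not m:
                    raise ValueError(f"malformed @attribute line: {line!r}")
                name = m.group(1) if m.group(1) is not None else m.group(2)
                spec = m.group(3).strip()
                kind = "nominal" if spec.startswith("{") else "numeric"
                attr_names.append(name)
                attr_kinds.append(kind)
            elif low.startswith("@data"):
                in_data = True
    if label_column not in attr_names:
        raise ValueError(f"label column {label_column!r} not declared in {path.name}")
    li = attr_names.index(label_column)
    if attr_kinds[li] != "nominal":
        raise ValueError(f"label attribute {label_column!r} must be nominal")
    gene_ids = [n for i, n in enumerate(attr_names) if i != li]
    matrix = np.empty((len(rows), len(gene_ids)), dtype=float)
    labels = np.empty(len(rows), dtype=object)
    for r, toks in enumerate(rows):
        if len(toks) != len(attr_names):
            raise ValueError(f"ARFF data row {r} has {len(toks)} fields, expected {len(attr_names)}")
        labels[r] = toks[li]
        vals = [toks[i] for i in range(len(toks)) if i != li]
        try:
            matrix[r] = [float(v) for v in vals]
        except ValueError as e:
            raise ValueError(f"non-numeric value in ARFF data row {r}: {e}") from None
    sample_ids = [f"s{r}" for r in range(len(rows))]
    return ExpressionDataset(matrix=matrix, gene_ids=gene_ids, sample_ids=sample_ids, labels=labels)


def _save_arff(data: ExpressionDataset, path: Path, label_column: str) -> None:
    classes = sorted(set(data.labels.tolist()))
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("@relation expression\n\n")
        for g in data.gene_ids:
            fh.write(f"@attribute '{g}' numeric\n")
        fh.write(f"@attribute '{label_column}' {{{','.join(classes)}}}\n\n@data\n")
        for i in range(data.n_samples):
            vals = ",".join(repr(float(v)) for v in data.matrix[i])
            fh.write(f"{vals},{data.labels[i]}\n")


def fit_normalizer(train: ExpressionDataset, scope: str = "train-only") -> NormalizationModel:
    """Compute per-gene min and max on the given data.

    ``scope`` is a provenance marker only ("train-only" or "full"); pass the
    matching data for it.
    """
    if train.n_samples == 0:
        raise ValueError("cannot fit a normalizer on an empty dataset")
    if scope not in ("train-only", "full"):
        raise ValueError(f"unknown normalization scope {scope!r}")
    return NormalizationModel(
        gene_ids=list(train.gene_ids),
        mins=train.matrix.min(axis=0),
        maxs=train.matrix.max(axis=0),
        fitted_on=scope,
        n_fit_samples=train.n_samples,
    )


def apply_normalizer(model: NormalizationModel, data: ExpressionDataset) -> ExpressionDataset:
    """Rescale every gene by its fitted (min, max): x' = (x - min)/(max - min).

    Constant genes (max == min) map to 0. Out-of-range values extrapolate
    linearly outside [0, 1] and are not clipped.
    """
    if model.gene_ids != data.gene_ids:
        raise ValueError("gene ids of data do not match the normalizer's fitting set")
    span = model.maxs - model.mins
    safe = np.where(span == 0, 1.0, span)
    scaled = (data.matrix - model.mins) / safe
    scaled[:, span == 0] = 0.0
    return ExpressionDataset(
        matrix=scaled,
        gene_ids=list(data.gene_ids),
        sample_ids=list(data.sample_ids),
        labels=data.labels.copy(),
    )


def class_distribution(data: ExpressionDataset) -> ClassDistribution:
    """Exact per-class counts with majority/minority classes (name-order tie-break)."""
    if data.n_samples == 0:
        raise ValueError("labels are empty")
    counts = Counter(data.labels.tolist())
    ordered = sorted(counts, key=str)  # class-name order for deterministic tie-breaks
    majority = sorted(ordered, key=lambda c: (-counts[c], str(c)))[0]
    minority = sorted(ordered, key=lambda c: (counts[c], str(c)))[0]
    return ClassDistribution(counts=dict(counts), majority_class=majority, minority_class=minority)


def fixed_holdout_split(
    data: ExpressionDataset, train_index_set: Sequence[int]
) -> tuple[ExpressionDataset, ExpressionDataset]:
    """Partition samples into (train, test) by an explicit train index set."""
    idx = np.asarray(sorted(set(int(i) for i in train_index_set)), dtype=int)
    if idx.size == 0:
        raise ValueError("train index set is empty")
    if idx.min() < 0 or idx.max() >= data.n_samples:
        raise IndexError(f"train index out of range for {data.n_samples} samples")
    mask = np.zeros(data.n_samples, dtype=bool)
    mask[idx] = True
    train = data.subset_samples(np.flatnonzero(mask))
    test = data.subset_samples(np.flatnonzero(~mask))
    if test.n_samples == 0:
        warnings.warn("holdout split has an empty test set", stacklevel=2)
    return train, test
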