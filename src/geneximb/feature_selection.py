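"""Filter gene selection: chi-square and information-gain ranking on
discretized expression, threshold-zero filtering, top-N selection, and the
ChiSIG intersection of the two rankings.

Continuous intensities are discretized per gene before scoring, by default
with supervised recursive entropy partitioning under the minimum description
length (MDL) stopping rule: a binary cut is accepted only when its information
gain exceeds ``(log2(N-1) + log2(3^c - 2) - c*H(S) + c1*H(S1) + c2*H(S2)) / N``
where ``c`` counts the classes present in the node and ``c1, c2`` those in the
two halves. Genes on which no cut is accepted collapse to a single bin and
score zero under both statistics — the discretizer doubles as a noise filter.

chi-square: sum over the bin x class contingency table of (O - E)^2 / E.
information gain: H(class) - H(class | bin), in bits. Both are nonnegative,
so the "threshold of zero" filter keeps strictly positive scores.

ChiSIG keeps the genes selected by *both* rankings, ordered by their
chi-square rank; its size is bounded by the smaller of the two input sets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .expression_data import ExpressionDataset

__all__ = [
    "DiscretizationModel",
    "GeneRanking",
    "GeneSet",
    "discretize",
    "apply_discretization",
    "chi_square_scores",
    "info_gain_scores",
    "select_positive",
    "select_top_n",
    "chisig_intersect",
]


@dataclass
class DiscretizationModel:
    """Per-gene ordered cut points; an empty list collapses the gene to one bin."""

    cut_points: Mapping[str, np.ndarray]
    method: str  # "mdl" | "equal_width"

    def __post_init__(self) -> None:
        for g, cuts in self.cut_points.items():
            c = np.asarray(cuts, dtype=float)
            if c.size > 1 and not np.all(np.diff(c) > 0):
                raise ValueError(f"cut points for gene {g!r} must be strictly increasing")


@dataclass
class GeneRanking:
    """(gene_id, score) pairs sorted by non-increasing score, ties by gene id."""

    entries: list[tuple[str, float]]
    method: str  # "chis" | "ig"

    def __post_init__(self) -> None:
        if any(s < 0 for _, s in self.entries):
            raise ValueError("scores must be nonnegative")
        self.entries = sorted(self.entries, key=lambda e: (-e[1], e[0]))

    def scores(self) -> dict[str, float]:
        return dict(self.entries)


@dataclass(frozen=True)
class GeneSet:
    """A named, ordered, duplicate-free gene subset."""

    name: str
    gene_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("gene set contains duplicates")

    def __len__(self) -> int:
        return len(self.gene_ids)

    def __contains__(self, g: str) -> bool:
        return g in set(self.gene_ids)


def _entropy(counts: np.ndarray) -> float:
    n = counts.sum()
    if n == 0:
        return 0.0
    p = counts[counts > 0] / n
    return float(-(p * np.log2(p)).sum())


def _class_counts(y_codes: np.ndarray, n_classes: int) -> np.ndarray:
    return np.bincount(y_codes, minlength=n_classes)


def _mdl_cuts(values: np.ndarray, y_codes: np.ndarray, n_classes: int) -> list[float]:
    """Fayyad–Irani recursive binary partitioning with the MDL stopping rule."""
    order = np.argsort(values, kind="stable")
    v = values[order]
    y = y_codes[order]
    cuts: list[float] = []

    def recurse(lo: int, hi: int) -> None:
        # candidate boundaries: midpoints between distinct adjacent values
        seg_v = v[lo:hi]
        seg_y = y[lo:hi]
        n = hi - lo
        if n < 2:
            return
        total = _class_counts(seg_y, n_classes)
        h_s = _entropy(total)
        if h_s == 0.0:
            return
        # prefix class counts for O(1) split evaluation
        one_hot = np.zeros((n, n_classes), dtype=np.int64)
        one_hot[np.arange(n), seg_y] = 1
        prefix = np.vstack([np.zeros((1, n_classes), dtype=np.int64), np.cumsum(one_hot, axis=0)])
        boundary = np.flatnonzero(seg_v[1:] > seg_v[:-1]) + 1  # split before index i
        if boundary.size == 0:
            return
        lefts = prefix[boundary].astype(float)
        rights = total.astype(float) - lefts
        nl = boundary.astype(float)
        nr = n - nl
        with np.errstate(invalid="ignore", divide="ignore"):
            pl = lefts / nl[:, None]
            pr = rights / nr[:, None]
            hl = -np.nansum(np.where(pl > 0, pl * np.log2(pl), 0.0), axis=1)
            hr = -np.nansum(np.where(pr > 0, pr * np.log2(pr), 0.0), axis=1)
        gains = h_s - (nl / n) * hl - (nr / n) * hr
        b = int(np.argmax(gains))
        best_gain, best_i = float(gains[b]), int(boundary[b])
        left = prefix[best_i]
        right = total - left
        c = int((total > 0).sum())
        c1 = int((left > 0).sum())
        c2 = int((right > 0).sum())
        delta = (
            np.log2(3**c - 2)
            - c * h_s
            + c1 * _entropy(left)
            + c2 * _entropy(right)
        )
        threshold = (np.log2(n - 1) + delta) / n
        if best_gain <= threshold:
            return
        cuts.append(float((v[lo + best_i - 1] + v[lo + best_i]) / 2.0))
        recurse(lo, lo + best_i)
        recurse(lo + best_i, hi)

    recurse(0, len(v))
    return sorted(cuts)


def discretize(
    train: ExpressionDataset, method: str = "mdl", max_bins: int = 10
) -> DiscretizationModel:
    """Fit per-gene cut points on labeled training data.

    ``method='mdl'`` (default) uses supervised entropy partitioning with MDL
    stopping; ``'equal_width'`` splits each gene's observed range into
    ``max_bins`` equal-width bins. Both are deterministic.
    """
    if method not in ("mdl", "equal_width"):
        raise ValueError(f"unknown discretization method {method!r}")
    classes = sorted(set(train.labels.tolist()), key=str)
    code = {c: i for i, c in enumerate(classes)}
    y_codes = np.array([code[c] for c in train.labels], dtype=np.int64)
    cut_points: dict[str, np.ndarray] = {}
    for j, g in enumerate(train.gene_ids):
        col = train.matrix[:, j]
        if method == "mdl":
            cuts = _mdl_cuts(col, y_codes, len(classes))
        else:
            lo, hi = float(col.min()), float(col.max())
            if hi <= lo:
                cuts = []
            else:
                cuts = list(np.linspace(lo, hi, max_bins + 1)[1:-1])
        cut_points[g] = np.asarray(cuts, dtype=float)
    return DiscretizationModel(cut_points=cut_points, method=method)


def apply_discretization(
    disc: DiscretizationModel, data: ExpressionDataset
) -> np.ndarray:
    """Bin indices per sample x gene (0-based; one bin when no cuts)."""
    out = np.empty(data.matrix.shape, dtype=np.int64)
    for j, g in enumerate(data.gene_ids):
        cuts = disc.cut_points[g]
        out[:, j] = np.searchsorted(cuts, data.matrix[:, j], side="right")
    return out


def _contingency(bins_col: np.ndarray, y_codes: np.ndarray, n_bins: int, n_classes: int) -> np.ndarray:
    table = np.zeros((n_bins, n_classes), dtype=np.int64)
    np.add.at(table, (bins_col, y_codes), 1)
    return table


def _rank_all(
    train: ExpressionDataset, disc: DiscretizationModel, statistic: str
) -> GeneRanking:
    missing = [g for g in train.gene_ids if g not in disc.cut_points]
    if missing:
        raise KeyError(f"discretization does not cover genes {missing[:5]}")
    classes = sorted(set(train.labels.tolist()), key=str)
    code = {c: i for i, c in enumerate(classes)}
    y_codes = np.array([code[c] for c in train.labels], dtype=np.int64)
    n = train.n_samples
    h_class = _entropy(np.bincount(y_codes, minlength=len(classes)))
    bins = apply_discretization(disc, train)
    entries: list[tuple[str, float]] = []
    for j, g in enumerate(train.gene_ids):
        n_bins = int(bins[:, j].max()) + 1
        if n_bins < 2:
            entries.append((g, 0.0))
            continue
        table = _contingency(bins[:, j], y_codes, n_bins, len(classes))
        if statistic == "chis":
            row = table.sum(axis=1, keepdims=True)
            col = table.sum(axis=0, keepdims=True)
            expected = row * col / n
            with np.errstate(invalid="ignore", divide="ignore"):
                terms = np.where(expected > 0, (table - expected) ** 2 / expected, 0.0)
            entries.append((g, float(terms.sum())))
        else:  # information gain, bits
            row = table.sum(axis=1)
            h_cond = sum(
                (row[b] / n) * _entropy(table[b]) for b in range(n_bins) if row[b] > 0
            )
            entries.append((g, max(0.0, float(h_class - h_cond))))
    return GeneRanking(entries=entries, method=statistic)


def chi_square_scores(train: ExpressionDataset, disc: DiscretizationModel) -> GeneRanking:
    """Per-gene chi-square statistic of the bin x class contingency table."""
    return _rank_all(train, disc, "chis")


def info_gain_scores(train: ExpressionDataset, disc: DiscretizationModel) -> GeneRanking:
    """Per-gene information gain H(class) - H(class | bin), in bits."""
    return _rank_all(train, disc, "ig")


def select_positive(ranking: GeneRanking) -> GeneSet:
    """Keep genes with strictly positive score, in ranking order."""
    ids = tuple(g for g, s in ranking.entries if s > 0)
    return GeneSet(name=f"{ranking.method}-positive", gene_ids=ids)


def select_top_n(ranking: GeneRanking, n: int) -> GeneSet:
    """First n genes of the positively-filtered ranking (all survivors with a
    warning when fewer than n score above zero)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    survivors = [g for g, s in ranking.entries if s > 0]
    if len(survivors) < n:
        warnings.warn(
            f"only {len(survivors)} genes score > 0; requested top-{n}", stacklevel=2
        )
    return GeneSet(name=f"{ranking.method}-top{n}", gene_ids=tuple(survivors[:n]))


def chisig_intersect(a: GeneSet, b: GeneSet) -> GeneSet:
    """Genes selected by both rankings, ordered by their rank in ``a``."""
    in_b = set(b.gene_ids)
    ids = tuple(g for g in a.gene_ids if g in in_b)
    if not ids:
        warnings.warn("ChiSIG intersection is empty; downstream stages need >= 1 gene", stacklevel=2)
    return GeneSet(name="chisig", gene_ids=ids)
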