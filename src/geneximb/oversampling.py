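"""SMOTE-family oversampling with balance-to-majority planning and provenance.

All resamplers here are implemented from algorithmic first principles:

* plain SMOTE — interpolate between a minority seed and one of its k nearest
  minority neighbors,
* Borderline-SMOTE B1/B2 — seed only from "danger" (borderline) minority
  samples; B2 also interpolates part-way toward majority neighbors,
* SVM-SMOTE — seed from the minority support vectors of a soft-margin SVM,
  interpolating or extrapolating depending on the local neighborhood,
* KMeans-SMOTE — cluster first, then apportion synthetic samples across
  minority-dominated clusters by sparsity and run SMOTE within each cluster.

Multiclass data are handled one-vs-rest: each non-majority class is
oversampled in turn with every other class pooled as "majority" for the
neighborhood rules. Every synthetic sample carries provenance
``(seed_index, neighbor_index, gap)`` such that
``values == seed + gap * (neighbor - seed)`` holds exactly on every
coordinate; a negative gap marks the extrapolation step of SVM-SMOTE
(``new = seed + |gap| * (seed - neighbor)``).

The balance-to-majority plan raises every class's training count to the
majority class's count, the target the evaluated study conditions use.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy.spatial.distance import pdist
from sklearn.cluster import KMeans
from sklearn.neighbors import NearestNeighbors
from sklearn.svm import SVC

from .expression_data import ClassDistribution, ExpressionDataset

__all__ = [
    "ResamplingPlan",
    "SyntheticSample",
    "plan_balance_to_majority",
    "smote",
    "classify_neighborhoods",
    "borderline_smote",
    "svm_smote",
    "kmeans_smote",
    "OVERSAMPLERS",
    "apply_oversampler",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ResamplingPlan:
    """Per-class target counts; every target is at least the original count."""

    target_counts: Mapping[str, int]

    def need(self, dist: ClassDistribution) -> dict[str, int]:
        """Synthetic samples required per class: target - original count."""
        out = {}
        for cls, target in self.target_counts.items():
            have = dist.counts.get(cls, 0)
            if target < have:
                raise ValueError(f"target {target} for class {cls!r} below its count {have}")
            out[cls] = target - have
        return out


@dataclass
class SyntheticSample:
    """Provenance of one generated sample.

    ``values == seed + gap * (neighbor - seed)`` exactly; ``gap`` is in [0, 1]
    for interpolation and in [-1, 0) for SVM-SMOTE extrapolation.
    """

    values: np.ndarray
    label: str
    seed_index: int
    neighbor_index: int
    gap: float

    def replay(self, train_matrix: np.ndarray) -> np.ndarray:
        s = train_matrix[self.seed_index]
        nb = train_matrix[self.neighbor_index]
        return s + self.gap * (nb - s)


def plan_balance_to_majority(dist: ClassDistribution) -> ResamplingPlan:
    """Set every class's target to the majority-class count."""
    if len(dist.counts) < 2:
        raise ValueError("balance-to-majority requires at least 2 classes")
    target = dist.majority_count
    return ResamplingPlan(target_counts={cls: target for cls in dist.counts})


def _append(
    train: ExpressionDataset, synths: list[SyntheticSample]
) -> ExpressionDataset:
    if not synths:
        return ExpressionDataset(
            matrix=train.matrix.copy(),
            gene_ids=list(train.gene_ids),
            sample_ids=list(train.sample_ids),
            labels=train.labels.copy(),
        )
    new_rows = np.vstack([s.values for s in synths])
    new_ids = [f"synth_{s.label}_{i}" for i, s in enumerate(synths)]
    return ExpressionDataset(
        matrix=np.vstack([train.matrix, new_rows]),
        gene_ids=list(train.gene_ids),
        sample_ids=list(train.sample_ids) + new_ids,
        labels=np.concatenate([train.labels, np.array([s.label for s in synths], dtype=object)]),
    )


def _interpolate(
    X: np.ndarray,
    seed_abs: int,
    neighbor_abs: int,
    gap: float,
    label: str,
) -> SyntheticSample:
    s, nb = X[seed_abs], X[neighbor_abs]
    return SyntheticSample(
        values=s + gap * (nb - s),
        label=label,
        seed_index=seed_abs,
        neighbor_index=neighbor_abs,
        gap=gap,
    )


def _minority_knn(X: np.ndarray, idx: np.ndarray, k: int) -> tuple[int, np.ndarray]:
    """k nearest within-class neighbors (absolute indices), self excluded.

    Returns the effective k (clamped to class size - 1) and an array of shape
    (len(idx), k_eff)."""
    n = len(idx)
    k_eff = min(k, n - 1)
    if k_eff < k:
        warnings.warn(f"k={k} clamped to {k_eff} (class has {n} samples)", stacklevel=3)
    nn = NearestNeighbors(n_neighbors=k_eff + 1).fit(X[idx])
    _, loc = nn.kneighbors(X[idx])
    # drop self (first column; NearestNeighbors returns self at distance 0 first
    # for distinct points — guard against duplicates by filtering explicitly)
    neigh = np.empty((n, k_eff), dtype=int)
    for i in range(n):
        row = [j for j in loc[i] if j != i][:k_eff]
        while len(row) < k_eff:  # duplicate points can hide the self index
            row.append(row[-1])
        neigh[i] = idx[np.asarray(row)]
    return k_eff, neigh


def _generate_from_seeds(
    X: np.ndarray,
    seed_pool: np.ndarray,
    neighbors_of: dict[int, np.ndarray],
    n_needed: int,
    label: str,
    rng: np.random.Generator,
    gap_high: float = 1.0,
) -> list[SyntheticSample]:
    """Cycle the seed pool in index order, drawing one neighbor and one gap per
    needed sample."""
    out: list[SyntheticSample] = []
    pool = np.sort(seed_pool)
    for i in range(n_needed):
        seed_abs = int(pool[i % len(pool)])
        nbrs = neighbors_of[seed_abs]
        nb_abs = int(nbrs[rng.integers(len(nbrs))])
        gap = float(rng.uniform(0.0, gap_high))
        out.append(_interpolate(X, seed_abs, nb_abs, gap, label))
    return out


def smote(
    train: ExpressionDataset,
    plan: ResamplingPlan,
    k: int = 5,
    seed: int = 0,
    allow_duplicate_fallback: bool = False,
) -> tuple[ExpressionDataset, list[SyntheticSample]]:
    """Plain SMOTE: new = seed + gap * (neighbor - seed), gap ~ U(0, 1),
    neighbor drawn among the seed's k nearest same-class neighbors (Euclidean).

    Originals are untouched and come first in the augmented dataset. A class of
    size 1 needing synthesis raises unless ``allow_duplicate_fallback``.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    from .expression_data import class_distribution

    dist = class_distribution(train)
    need = plan.need(dist)
    rng = np.random.default_rng(seed)
    X = train.matrix
    synths: list[SyntheticSample] = []
    for cls in sorted(need, key=str):
        n_needed = need[cls]
        if n_needed == 0:
            continue
        idx = np.flatnonzero(train.labels == cls)
        if len(idx) < 2:
            if not allow_duplicate_fallback:
                raise ValueError(
                    f"class {cls!r} has {len(idx)} sample(s); SMOTE needs >= 2 "
                    "(use allow_duplicate_fallback to duplicate instead)"
                )
            only = int(idx[0])
            synths.extend(
                _interpolate(X, only, only, 0.0, cls) for _ in range(n_needed)
            )
            continue
        _, neigh = _minority_knn(X, idx, k)
        nb_map = {int(a): neigh[i] for i, a in enumerate(idx)}
        synths.extend(_generate_from_seeds(X, idx, nb_map, n_needed, cls, rng))
    return _append(train, synths), synths


def classify_neighborhoods(
    train: ExpressionDataset, minority_class: str, m: int = 10
) -> dict[int, str]:
    """Label each minority sample safe / danger / noise by its m nearest
    whole-set neighbors (self excluded).

    With m' = majority-class neighbors among the m: noise if m' == m, danger if
    m/2 <= m' < m, safe if m' < m/2.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    X = train.matrix
    min_idx = np.flatnonzero(train.labels == minority_class)
    m_eff = min(m, train.n_samples - 1)
    if m_eff < m:
        warnings.warn(f"m={m} clamped to {m_eff}", stacklevel=2)
    nn = NearestNeighbors(n_neighbors=m_eff + 1).fit(X)
    _, loc = nn.kneighbors(X[min_idx])
    out: dict[int, str] = {}
    for i, abs_i in enumerate(min_idx):
        nbrs = [j for j in loc[i] if j != abs_i][:m_eff]
        m_maj = sum(1 for j in nbrs if train.labels[j] != minority_class)
        if m_maj == m_eff:
            out[int(abs_i)] = "noise"
        elif 2 * m_maj >= m_eff:
            out[int(abs_i)] = "danger"
        else:
            out[int(abs_i)] = "safe"
    return out


def borderline_smote(
    train: ExpressionDataset,
    plan: ResamplingPlan,
    k: int = 5,
    m: int = 10,
    variant: str = "B1",
    seed: int = 0,
) -> tuple[ExpressionDataset, list[SyntheticSample]]:
    """Borderline-SMOTE: seeds are drawn only from the danger (borderline) set.

    B1 interpolates toward k-nearest same-class neighbors with gap ~ U(0, 1).
    B2 additionally directs half the draws toward nearest majority neighbors
    with gap ~ U(0, 0.5), keeping new samples on the minority side. If a class
    has no danger samples, that class falls back to plain SMOTE seeding with a
    logged warning.
    """
    if variant not in ("B1", "B2"):
        raise ValueError(f"variant must be 'B1' or 'B2', got {variant!r}")
    from .expression_data import class_distribution

    dist = class_distribution(train)
    need = plan.need(dist)
    rng = np.random.default_rng(seed)
    X = train.matrix
    synths: list[SyntheticSample] = []
    for cls in sorted(need, key=str):
        n_needed = need[cls]
        if n_needed == 0:
            continue
        idx = np.flatnonzero(train.labels == cls)
        if len(idx) < 2:
            raise ValueError(f"class {cls!r} needs >= 2 samples for Borderline-SMOTE")
        categories = classify_neighborhoods(train, cls, m)
        danger = np.array([i for i in idx if categories[int(i)] == "danger"], dtype=int)
        if danger.size == 0:
            warnings.warn(
                f"class {cls!r}: empty danger set, falling back to plain SMOTE seeds",
                stacklevel=2,
            )
            danger = idx
        _, neigh_min = _minority_knn(X, idx, k)
        nb_min = {int(a): neigh_min[i] for i, a in enumerate(idx)}
        if variant == "B1":
            synths.extend(_generate_from_seeds(X, danger, nb_min, n_needed, cls, rng))
            continue
        # B2: alternate between minority-directed U(0,1) and majority-directed
        # U(0,0.5) draws, one coin flip per synthetic sample
        maj_idx = np.flatnonzero(train.labels != cls)
        k_maj = min(k, len(maj_idx))
        nn_maj = NearestNeighbors(n_neighbors=k_maj).fit(X[maj_idx])
        _, loc_maj = nn_maj.kneighbors(X[danger])
        maj_map = {int(d): maj_idx[loc_maj[i]] for i, d in enumerate(danger)}
        pool = np.sort(danger)
        for i in range(n_needed):
            seed_abs = int(pool[i % len(pool)])
            if rng.random() < 0.5:
                nbrs = nb_min[seed_abs]
                gap = float(rng.uniform(0.0, 1.0))
            else:
                nbrs = maj_map[seed_abs]
                gap = float(rng.uniform(0.0, 0.5))
            nb_abs = int(nbrs[rng.integers(len(nbrs))])
            synths.append(_interpolate(X, seed_abs, nb_abs, gap, cls))
    return _append(train, synths), synths


def svm_smote(
    train: ExpressionDataset,
    plan: ResamplingPlan,
    k: int = 5,
    m: int = 10,
    seed: int = 0,
    svm_regularization: float = 1.0,
) -> tuple[ExpressionDataset, list[SyntheticSample]]:
    """SVM-SMOTE: seeds are the minority support vectors of a soft-margin SVM
    (linear kernel, one-vs-rest per class).

    For each seed, if a majority of its m nearest whole-set neighbors belong to
    other classes the new sample interpolates toward a same-class neighbor
    (gap ~ U(0,1)); otherwise it extrapolates away from it,
    ``new = seed + g * (seed - neighbor)``, recorded with gap = -g so
    provenance replays exactly.
    """
    from .expression_data import class_distribution

    dist = class_distribution(train)
    need = plan.need(dist)
    rng = np.random.default_rng(seed)
    X = train.matrix
    n_all = train.n_samples
    m_eff = min(m, n_all - 1)
    nn_all = NearestNeighbors(n_neighbors=m_eff + 1).fit(X)
    synths: list[SyntheticSample] = []
    for cls in sorted(need, key=str):
        n_needed = need[cls]
        if n_needed == 0:
            continue
        idx = np.flatnonzero(train.labels == cls)
        if len(idx) < 2:
            raise ValueError(f"class {cls!r} needs >= 2 samples for SVM-SMOTE")
        y_bin = (train.labels == cls).astype(int)
        svc = SVC(kernel="linear", C=svm_regularization).fit(X, y_bin)
        sv = svc.support_[y_bin[svc.support_] == 1]
        if sv.size == 0:
            warnings.warn(
                f"class {cls!r}: no minority support vectors, falling back to plain SMOTE seeds",
                stacklevel=2,
            )
            sv = idx
        _, neigh_min = _minority_knn(X, idx, k)
        nb_min = {int(a): neigh_min[i] for i, a in enumerate(idx)}
        _, loc_all = nn_all.kneighbors(X[sv])
        danger_like: dict[int, bool] = {}
        for i, s_abs in enumerate(sv):
            nbrs = [j for j in loc_all[i] if j != s_abs][:m_eff]
            m_maj = sum(1 for j in nbrs if train.labels[j] != cls)
            danger_like[int(s_abs)] = 2 * m_maj > m_eff
        pool = np.sort(sv)
        for i in range(n_needed):
            seed_abs = int(pool[i % len(pool)])
            nbrs = nb_min[seed_abs]
            nb_abs = int(nbrs[rng.integers(len(nbrs))])
            g = float(rng.uniform(0.0, 1.0))
            gap = g if danger_like[seed_abs] else -g
            synths.append(_interpolate(X, seed_abs, nb_abs, gap, cls))
    return _append(train, synths), synths


def kmeans_smote(
    train: ExpressionDataset,
    plan: ResamplingPlan,
    n_clusters: int | None = None,
    minority_threshold: float = 0.5,
    density_exponent: float | None = None,
    seed: int = 0,
) -> tuple[ExpressionDataset, list[SyntheticSample]]:
    """KMeans-SMOTE: cluster the whole training set, then run plain SMOTE
    inside minority-dominated clusters.

    A cluster is eligible for a class if its within-cluster fraction of that
    class is >= ``minority_threshold`` and it holds >= 2 class samples. The
    class's synthetic budget is apportioned across eligible clusters
    proportionally to a sparsity weight (mean pairwise within-cluster minority
    distance raised to ``density_exponent``), with largest-remainder rounding
    so totals match the plan exactly. No eligible cluster -> plain-SMOTE
    fallback for that class.
    """
    from .expression_data import class_distribution

    dist = class_distribution(train)
    need = plan.need(dist)
    rng = np.random.default_rng(seed)
    X = train.matrix
    if n_clusters is None:
        n_clusters = max(2, min(8, train.n_samples // 2))
    if density_exponent is None:
        density_exponent = min(2.0, float(np.sqrt(train.n_genes)))
    km = KMeans(n_clusters=n_clusters, n_init=10, random_state=seed % (2**31)).fit(X)
    assign = km.labels_
    synths: list[SyntheticSample] = []
    for cls in sorted(need, key=str):
        n_needed = need[cls]
        if n_needed == 0:
            continue
        cls_mask = train.labels == cls
        eligible: list[tuple[int, np.ndarray, float]] = []
        for c in range(n_clusters):
            members = np.flatnonzero(assign == c)
            cls_members = members[cls_mask[members]]
            if len(members) == 0 or len(cls_members) < 2:
                continue
            frac = len(cls_members) / len(members)
            if frac >= minority_threshold:
                d = pdist(X[cls_members])
                sparsity = float(np.mean(d)) if d.size else 0.0
                eligible.append((c, cls_members, max(sparsity, 1e-12) ** density_exponent))
        if not eligible:
            warnings.warn(
                f"class {cls!r}: no eligible cluster, falling back to plain SMOTE",
                stacklevel=2,
            )
            idx = np.flatnonzero(cls_mask)
            if len(idx) < 2:
                raise ValueError(f"class {cls!r} needs >= 2 samples")
            _, neigh = _minority_knn(X, idx, 5)
            nb_map = {int(a): neigh[i] for i, a in enumerate(idx)}
            synths.extend(_generate_from_seeds(X, idx, nb_map, n_needed, cls, rng))
            continue
        weights = np.array([w for _, _, w in eligible])
        weights = weights / weights.sum()
        raw = weights * n_needed
        alloc = np.floor(raw).astype(int)
        remainder = n_needed - alloc.sum()
        order = np.argsort(-(raw - alloc), kind="stable")
        alloc[order[:remainder]] += 1
        for (c, cls_members, _), n_c in zip(eligible, alloc):
            if n_c == 0:
                continue
            _, neigh = _minority_knn(X, cls_members, 5)
            nb_map = {int(a): neigh[i] for i, a in enumerate(cls_members)}
            synths.extend(_generate_from_seeds(X, cls_members, nb_map, int(n_c), cls, rng))
    return _append(train, synths), synths


OVERSAMPLERS: dict[str, Callable] = {
    "smote": smote,
    "b1": lambda train, plan, seed=0, **kw: borderline_smote(train, plan, variant="B1", seed=seed, **kw),
    "b2": lambda train, plan, seed=0, **kw: borderline_smote(train, plan, variant="B2", seed=seed, **kw),
    "svm": svm_smote,
    "kmeans": kmeans_smote,
}


def apply_oversampler(
    method: str,
    train: ExpressionDataset,
    plan: ResamplingPlan | None = None,
    seed: int = 0,
    **kwargs,
) -> tuple[ExpressionDataset, list[SyntheticSample]]:
    """Dispatch by method name ('smote', 'b1', 'b2', 'svm', 'kmeans'); a None
    plan defaults to balance-to-majority."""
    if method not in OVERSAMPLERS:
        raise KeyError(f"unknown oversampler {method!r}; choose from {sorted(OVERSAMPLERS)}")
    if plan is None:
        from .expression_data import class_distribution

        plan = plan_balance_to_majority(class_distribution(train))
    return OVERSAMPLERS[method](train, plan, seed=seed, **kwargs)
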