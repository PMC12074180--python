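"""Hierarchical clustering of calibration-curve parameters.

Replicate calibration curves from different runs are summarised by their
fitted (slope, intercept) pairs and grouped by agglomerative clustering with
the Canberra distance and complete linkage.  The Canberra metric normalises
each coordinate by its magnitude, so slopes (~1e-2) and intercepts (~1e-2 to
1e-1) contribute comparably without explicit standardisation.  Cluster-count
selection scans candidate k with two validity indices — the Dunn index and
the mean silhouette width — and keeps the k they jointly favour.

The agglomeration is written out explicitly (it runs on a handful of curves)
so the merge order is fully deterministic: ties in merge height are broken by
the smallest pair of original curve indices.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import DegenerateInputError, UndefinedIndexError

__all__ = [
    "CurveFeatures",
    "MergeStep",
    "ClusteringResult",
    "canberra_distance",
    "pairwise_canberra",
    "complete_linkage",
    "cut_tree",
    "hierarchical_cluster",
    "dunn_index",
    "silhouette_score",
    "select_k",
]

#: Mean-silhouette level below which a partition is flagged low-confidence
#: (the conventional boundary under which structure is at best "weak and
#: could be artificial").
WEAK_STRUCTURE_SILHOUETTE = 0.5


@dataclass(frozen=True)
class CurveFeatures:
    """Feature vectors (one per curve) for clustering.

    ``feature_set`` names which parameters the vectors hold: the bivariate
    ``slope_intercept`` set drives the workflow; univariate ``slope`` and
    ``intercept`` variants are computed alongside for concordance checks.
    """

    curve_ids: tuple[str, ...]
    matrix: np.ndarray  # shape (m, d)
    feature_set: str = "slope_intercept"

    def __post_init__(self) -> None:
        m = np.atleast_2d(np.asarray(self.matrix, dtype=float))
        object.__setattr__(self, "matrix", m)
        if m.shape[0] != len(self.curve_ids):
            raise ValueError("one feature vector per curve required")
        if not np.all(np.isfinite(m)):
            raise ValueError("feature vectors must be finite")


@dataclass(frozen=True)
class MergeStep:
    """One agglomeration step in scipy-style cluster numbering.

    Original curves are clusters ``0..m-1``; the cluster produced by step
    ``i`` (0-based) gets id ``m + i``.
    """

    step: int
    left: int
    right: int
    height: float
    members: tuple[int, ...]


@dataclass(frozen=True)
class ClusteringResult:
    labels: np.ndarray
    merge_history: tuple[MergeStep, ...]
    dunn_by_k: dict[int, float]
    silhouette_by_k: dict[int, float]
    chosen_k: int
    low_confidence: bool
    feature_set: str = "slope_intercept"

    def to_dict(self) -> dict:
        return {
            "feature_set": self.feature_set,
            "chosen_k": self.chosen_k,
            "low_confidence": self.low_confidence,
            "labels": [int(v) for v in self.labels],
            "dunn_by_k": {int(k): v for k, v in self.dunn_by_k.items()},
            "silhouette_by_k": {int(k): v for k, v in self.silhouette_by_k.items()},
            "merges": [
                {"step": s.step, "left": s.left, "right": s.right, "height": s.height}
                for s in self.merge_history
            ],
        }


def canberra_distance(x: Sequence[float], y: Sequence[float]) -> float:
    """Canberra distance sum_i |x_i - y_i| / (|x_i| + |y_i|).

    A coordinate where both entries are exactly zero contributes zero.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape or xa.ndim != 1 or len(xa) < 1:
        raise ValueError(f"need equal-length 1-D vectors, got {xa.shape} vs {ya.shape}")
    num = np.abs(xa - ya)
    den = np.abs(xa) + np.abs(ya)
    with np.errstate(invalid="ignore"):
        terms = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    return float(terms.sum())


def pairwise_canberra(matrix: np.ndarray) -> np.ndarray:
    """Symmetric (m, m) Canberra distance matrix."""
    m = len(matrix)
    d = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            d[i, j] = d[j, i] = canberra_distance(matrix[i], matrix[j])
    return d


def complete_linkage(features: CurveFeatures) -> tuple[MergeStep, ...]:
    """Full agglomeration under complete linkage and Canberra distance.

    Inter-cluster distance is the maximum pairwise point distance.  At every
    step the pair of active clusters with the smallest distance merges; on
    equal heights the pair containing the smallest original indices wins, so
    the output is a pure function of the input order.
    """
    dmat = pairwise_canberra(features.matrix)
    m = len(features.curve_ids)
    active: dict[int, tuple[int, ...]] = {i: (i,) for i in range(m)}
    steps: list[MergeStep] = []
    next_id = m
    for step in range(m - 1):
        best = None
        for a in sorted(active):
            for b in sorted(active):
                if b <= a:
                    continue
                h = max(dmat[i, j] for i in active[a] for j in active[b])
                lo_a, lo_b = min(active[a]), min(active[b])
                key = (h, min(lo_a, lo_b), max(lo_a, lo_b))
                if best is None or key < best[0]:
                    best = (key, a, b, h)
        _, a, b, h = best
        members = tuple(sorted(active[a] + active[b]))
        steps.append(MergeStep(step=step, left=a, right=b, height=h, members=members))
        del active[a], active[b]
        active[next_id] = members
        next_id += 1
    return tuple(steps)


def cut_tree(merges: Sequence[MergeStep], m: int, k: int) -> np.ndarray:
    """Labels from stopping the agglomeration at k clusters.

    Labels are renumbered 0..k-1 in order of each cluster's smallest member.
    """
    if not (1 <= k <= m):
        raise ValueError(f"k must be in [1, {m}], got {k}")
    active: dict[int, tuple[int, ...]] = {i: (i,) for i in range(m)}
    next_id = m
    for s in merges:
        if len(active) == k:
            break
        members = active.pop(s.left) + active.pop(s.right)
        active[next_id] = tuple(sorted(members))
        next_id += 1
    labels = np.empty(m, dtype=int)
    groups = sorted(active.values(), key=min)
    for lab, members in enumerate(groups):
        for i in members:
            labels[i] = lab
    return labels


def hierarchical_cluster(features: CurveFeatures, k: int) -> np.ndarray:
    """Complete-linkage Canberra clustering cut at k groups."""
    m = len(features.curve_ids)
    if k > m:
        raise DegenerateInputError(f"k={k} exceeds number of curves m={m}")
    return cut_tree(complete_linkage(features), m, k)


def _check_partition(labels: np.ndarray) -> list[np.ndarray]:
    labs = np.asarray(labels)
    groups = [np.flatnonzero(labs == g) for g in np.unique(labs)]
    if len(groups) < 2:
        raise DegenerateInputError("validity indices need >=2 clusters")
    return groups


def dunn_index(features: CurveFeatures, labels: Sequence[int]) -> float:
    """Minimum between-cluster distance over maximum within-cluster diameter.

    Larger values indicate compact, well-separated clusters.  Undefined when
    every cluster is a singleton (or all within-cluster points coincide),
    since the maximum diameter is then zero.
    """
    groups = _check_partition(np.asarray(labels))
    d = pairwise_canberra(features.matrix)
    max_diam = 0.0
    for g in groups:
        if len(g) >= 2:
            max_diam = max(max_diam, max(d[i, j] for i in g for j in g if i < j))
    if max_diam == 0.0:
        raise UndefinedIndexError("all clusters have zero diameter; Dunn undefined")
    min_between = min(
        d[i, j]
        for gi in range(len(groups))
        for gj in range(gi + 1, len(groups))
        for i in groups[gi]
        for j in groups[gj]
    )
    return min_between / max_diam


def silhouette_score(features: CurveFeatures, labels: Sequence[int]) -> float:
    """Mean silhouette width under the Canberra distance.

    Per point, s = (b - a)/max(a, b) with a the mean distance to own-cluster
    co-members and b the smallest mean distance to another cluster; points in
    singleton clusters contribute s = 0.
    """
    labs = np.asarray(labels)
    groups = _check_partition(labs)
    m = len(labs)
    if len(groups) > m - 1:
        raise DegenerateInputError("silhouette needs k <= m-1")
    d = pairwise_canberra(features.matrix)
    s = np.zeros(m)
    for i in range(m):
        own = np.flatnonzero(labs == labs[i])
        if len(own) == 1:
            s[i] = 0.0
            continue
        a = d[i, own[own != i]].mean()
        b = min(
            d[i, np.flatnonzero(labs == g)].mean()
            for g in np.unique(labs)
            if g != labs[i]
        )
        denom = max(a, b)
        s[i] = 0.0 if denom == 0 else (b - a) / denom
    return float(s.mean())


def select_k(
    features: CurveFeatures, candidate_ks: Sequence[int] = (2, 3, 4, 5)
) -> ClusteringResult:
    """Scan candidate cluster counts and pick the jointly best one.

    Both indices are computed for every feasible k.  The chosen k maximises
    both when they agree; on disagreement the silhouette (bounded in [-1, 1]
    and hence comparable across k) wins.  A partition whose best silhouette
    stays below 0.5 is flagged low-confidence.
    """
    m = len(features.curve_ids)
    ks = sorted({int(k) for k in candidate_ks if 2 <= k <= m - 1})
    if not ks:
        raise DegenerateInputError(
            f"no feasible k in {list(candidate_ks)} for m={m} curves"
        )
    merges = complete_linkage(features)
    dunn_by_k: dict[int, float] = {}
    sil_by_k: dict[int, float] = {}
    for k in ks:
        labels = cut_tree(merges, m, k)
        try:
            dunn_by_k[k] = dunn_index(features, labels)
        except UndefinedIndexError:
            dunn_by_k[k] = float("nan")
        sil_by_k[k] = silhouette_score(features, labels)
    best_sil = max(ks, key=lambda k: sil_by_k[k])
    finite_dunn = {k: v for k, v in dunn_by_k.items() if np.isfinite(v)}
    best_dunn = max(finite_dunn, key=finite_dunn.get) if finite_dunn else best_sil
    chosen = best_sil  # silhouette wins on disagreement; equals best_dunn otherwise
    return ClusteringResult(
        labels=cut_tree(merges, m, chosen),
        merge_history=merges,
        dunn_by_k=dunn_by_k,
        silhouette_by_k=sil_by_k,
        chosen_k=chosen,
        low_confidence=sil_by_k[best_sil] < WEAK_STRUCTURE_SILHOUETTE,
        feature_set=features.feature_set,
    )


def merge_history_nested(merges: Sequence[MergeStep], curve_ids: Sequence[str]):
    """Nested-list rendering of the merge tree with curve ids at the leaves."""
    m = len(curve_ids)
    nodes: dict[int, object] = {i: curve_ids[i] for i in range(m)}
    for s in merges:
        nodes[m + s.step] = [nodes[s.left], nodes[s.right]]
    return nodes[m + len(merges) - 1] if merges else list(curve_ids)
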