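"""Agglomerative clustering of a distance matrix and threshold-ladder cuts.

Clusters of similar clonotypes are read off an agglomerative merge tree at a
fixed ladder of distance thresholds (default 0..50 in steps of 5). The
implementation is deliberately deterministic: clusters are labelled by the
smallest matrix index among their members, the next merge is always the
closest pair, and equal-height merges are resolved by the lexicographically
smallest label pair. Complete linkage is the default (it bounds the
within-cluster diameter, matching the homology-cluster intent); average and
single linkage are available.

``sweep`` cuts one dendrogram at every ladder threshold, so the resulting
partitions are nested by construction. Because merge heights are
non-decreasing for these linkages, the sweep only needs merges up to the
ladder maximum; items with no neighbour within that radius can never join a
cluster at any cut and are pre-pruned before agglomeration, which makes
sweeps over mostly-dissimilar repertoires (e.g. null trials) fast.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np

from .metric import DistanceMatrix

LINKAGES = ("complete", "average", "single")

DEFAULT_THRESHOLDS = (0, 5, 10, 15, 20, 25, 30, 35, 40, 45, 50)


@dataclass(frozen=True)
class ThresholdLadder:
    thresholds: Tuple[int, ...] = DEFAULT_THRESHOLDS

    def __post_init__(self) -> None:
        t = self.thresholds
        if not t:
            raise ValueError("empty threshold ladder")
        if any(b <= a for a, b in zip(t, t[1:])):
            raise ValueError("thresholds must be strictly increasing")

    @property
    def max(self) -> int:
        return self.thresholds[-1]

    def __iter__(self):
        return iter(self.thresholds)

    def __len__(self) -> int:
        return len(self.thresholds)


@dataclass(frozen=True)
class Dendrogram:
    """Merge tree: (label_a, label_b, height) with labels = smallest member index.

    ``stop_height`` marks a truncated tree containing only merges at height
    <= stop_height; cuts above it are refused.
    """

    n: int
    merges: Tuple[Tuple[int, int, float], ...]
    linkage: str
    stop_height: Optional[float] = None


@dataclass(frozen=True)
class ClusterAssignment:
    """Partition of matrix indices 0..n-1 at one threshold."""

    threshold: float
    clusters: Tuple[Tuple[int, ...], ...]

    @property
    def labels(self) -> np.ndarray:
        n = sum(len(c) for c in self.clusters)
        out = np.empty(n, dtype=np.int64)
        for cid, members in enumerate(self.clusters):
            for m in members:
                out[m] = cid
        return out

    def cluster_of(self) -> Dict[int, int]:
        return {m: cid for cid, members in enumerate(self.clusters) for m in members}


def _validated(d) -> np.ndarray:
    if isinstance(d, DistanceMatrix):  # already validated at construction
        return d.values.astype(float)
    values = np.asarray(d, dtype=float)
    if values.ndim != 2 or values.shape[0] != values.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(values, values.T):
        raise ValueError("distance matrix must be symmetric")
    if (np.diag(values) != 0).any():
        raise ValueError("distance matrix must have a zero diagonal")
    return values.astype(float)


def _agglomerate(values: np.ndarray, linkage: str,
                 stop_height: Optional[float]) -> List[Tuple[int, int, float]]:
    """Naive deterministic agglomeration over a full matrix copy.

    Row/col i always represents the cluster whose smallest member index is i,
    so a row-major argmin implements the smallest-label-pair tie-break.
    """
    n = values.shape[0]
    work = values.copy()
    np.fill_diagonal(work, np.inf)
    sizes = np.ones(n, dtype=np.int64)
    active = n
    merges: List[Tuple[int, int, float]] = []
    while active > 1:
        flat = int(np.argmin(work))
        i, j = divmod(flat, n)
        height = work[i, j]
        if not np.isfinite(height):
            break
        if stop_height is not None and height > stop_height:
            break
        if i > j:
            i, j = j, i
        merges.append((i, j, float(height)))
        row_i, row_j = work[i], work[j]
        if linkage == "complete":
            merged = np.maximum(row_i, row_j)
        elif linkage == "single":
            merged = np.minimum(row_i, row_j)
        elif linkage == "average":
            merged = (sizes[i] * row_i + sizes[j] * row_j) / (sizes[i] + sizes[j])
            # keep inf where a partner is retired
            merged[~np.isfinite(row_i)] = np.inf
        else:
            raise ValueError(f"unknown linkage {linkage!r}")
        work[i, :] = merged
        work[:, i] = merged
        work[i, i] = np.inf
        work[j, :] = np.inf
        work[:, j] = np.inf
        sizes[i] += sizes[j]
        active -= 1
    return merges


def build_dendrogram(d, linkage: str = "complete",
                     stop_height: Optional[float] = None) -> Dendrogram:
    """Deterministic agglomerative merge tree of a symmetric distance matrix."""
    if linkage not in LINKAGES:
        raise ValueError(f"linkage must be one of {LINKAGES}")
    values = _validated(d)
    merges = _agglomerate(values, linkage, stop_height)
    return Dendrogram(n=values.shape[0], merges=tuple(merges),
                      linkage=linkage, stop_height=stop_height)


def _pruned_dendrogram(values: np.ndarray, linkage: str, stop: float) -> Dendrogram:
    """Dendrogram truncated at ``stop``, agglomerating only items that have a
    neighbour within ``stop`` (others provably stay singletons at cuts <= stop)."""
    n = values.shape[0]
    off = values + np.where(np.eye(n, dtype=bool), np.inf, 0.0)
    keep = np.where((off <= stop).any(axis=1))[0]
    if len(keep) < 2:
        return Dendrogram(n=n, merges=(), linkage=linkage, stop_height=stop)
    sub = values[np.ix_(keep, keep)]
    merges = _agglomerate(sub, linkage, stop)
    remapped = tuple((int(keep[a]), int(keep[b]), h) for a, b, h in merges)
    return Dendrogram(n=n, merges=remapped, linkage=linkage, stop_height=stop)


def cut_at_threshold(dendro: Dendrogram, t: float) -> ClusterAssignment:
    """Height-inclusive cut: members join iff linked by merges at height <= t."""
    if t < 0:
        raise ValueError("threshold must be >= 0")
    if dendro.stop_height is not None and t > dendro.stop_height:
        raise ValueError(
            f"cut at {t} above the dendrogram's stop height {dendro.stop_height}")
    parent = list(range(dendro.n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b, h in dendro.merges:
        if h <= t:
            ra, rb = find(a), find(b)
            if ra != rb:
                parent[max(ra, rb)] = min(ra, rb)
    groups: Dict[int, List[int]] = {}
    for idx in range(dendro.n):
        groups.setdefault(find(idx), []).append(idx)
    clusters = tuple(tuple(groups[r]) for r in sorted(groups))
    return ClusterAssignment(threshold=t, clusters=clusters)


def sweep(d, ladder: ThresholdLadder = ThresholdLadder(),
          linkage: str = "complete") -> List[ClusterAssignment]:
    """One ClusterAssignment per ladder threshold, from a single dendrogram."""
    if linkage not in LINKAGES:
        raise ValueError(f"linkage must be one of {LINKAGES}")
    values = _validated(d)
    dendro = _pruned_dendrogram(values, linkage, float(ladder.max))
    return [cut_at_threshold(dendro, t) for t in ladder]
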