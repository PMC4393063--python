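"""Agglomerative Ward clustering of components on 1 - CoCo dissimilarity.

The CoCo dissimilarity is not Euclidean; it is fed to the Ward
Lance-Williams recurrence by treating ``1 - CoCo`` as a *squared*
inter-object distance (the linkage therefore receives
``sqrt(1 - CoCo)``).  Ward heights are then monotone non-decreasing, and
the sequence of merge heights — the merge-distance profile ``d_k`` for
k = 2..n, where ``d_k`` is the cost of merging k clusters into k-1 —
is the statistic later compared against a uniform null to choose the
number of clusters.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .similarity import SimilarityMatrix

__all__ = ["Dendrogram", "MergeDistanceProfile", "ward_cluster",
           "ward_linkage_from_dissimilarity", "merge_profile", "cut"]


@dataclass(frozen=True)
class Dendrogram:
    """Ward merge tree in the standard linkage-matrix layout
    (child-a, child-b, height, member-count) plus the leaf ids."""

    linkage: np.ndarray  # (n-1, 4)
    leaf_ids: Tuple[str, ...]
    frequencies: Optional[np.ndarray] = None  # per-leaf representative Hz

    def __post_init__(self):
        n = len(self.leaf_ids)
        if self.linkage.shape != (n - 1, 4):
            raise ValueError("linkage must have n-1 rows")
        heights = self.linkage[:, 2]
        if np.any(np.diff(heights) < -1e-9):
            raise ValueError("Ward heights must be non-decreasing")

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_ids)

    def to_newick(self) -> str:
        """Newick string with branch lengths derived from merge heights."""
        n = self.n_leaves
        height = np.concatenate([np.zeros(n), self.linkage[:, 2]])
        names = {i: self.leaf_ids[i] for i in range(n)}
        for k, (a, b, h, _) in enumerate(self.linkage):
            a, b = int(a), int(b)
            la, lb = h - height[a], h - height[b]
            names[n + k] = f"({names.pop(a)}:{la:g},{names.pop(b)}:{lb:g})"
        return names[2 * n - 2] + ";"


@dataclass(frozen=True)
class MergeDistanceProfile:
    """Merge heights indexed by the number of clusters being reduced:
    ``heights[i]`` is d_k for k = ks[i], the height of the merge taking
    k clusters to k-1.  d_2 is the final (largest) merge."""

    ks: np.ndarray  # (2, 3, ..., n)
    heights: np.ndarray

    def __post_init__(self):
        if self.ks.shape != self.heights.shape:
            raise ValueError("ks and heights must be congruent")
        if np.any(self.heights < 0):
            raise ValueError("merge heights must be non-negative")

    def d(self, k: int) -> float:
        i = np.flatnonzero(self.ks == k)
        if i.size == 0:
            raise KeyError(f"no merge for k={k}")
        return float(self.heights[i[0]])


def ward_linkage_from_dissimilarity(d: np.ndarray) -> np.ndarray:
    """Ward linkage treating the entries of ``d`` as squared
    inter-object distances."""
    condensed = squareform(np.sqrt(np.maximum(d, 0.0)), checks=False)
    return hierarchy.linkage(condensed, method="ward")


def ward_cluster(sim: SimilarityMatrix) -> Dendrogram:
    """Cluster components agglomeratively with Ward linkage on the
    1 - CoCo dissimilarity."""
    if len(sim) < 2:
        raise ValueError("at least two components are required")
    Z = ward_linkage_from_dissimilarity(sim.dissimilarity())
    freqs = None
    try:  # ids of the form gene|frequency|span carry the frequency
        freqs = np.array([float(i.split("|")[1]) for i in sim.ids])
    except (IndexError, ValueError):
        pass
    return Dendrogram(linkage=Z, leaf_ids=sim.ids, frequencies=freqs)


def merge_profile(dend: Dendrogram) -> MergeDistanceProfile:
    """Merge-distance profile d_k, k = 2..n: the merge reducing k
    clusters to k-1 is merge number n-k+1 in ascending-height order."""
    n = dend.n_leaves
    heights = np.sort(dend.linkage[:, 2])
    # heights[i] is merge i+1; merge n-k+1 has index n-k
    ks = np.arange(2, n + 1)
    return MergeDistanceProfile(ks=ks, heights=heights[n - ks])


def cut(dend: Dendrogram, k: int) -> np.ndarray:
    """Labels from removing the k-1 largest merges.

    Cluster ids are 0..k-1 ordered by ascending cluster median
    frequency when leaf frequencies are known (ascending first-leaf
    index otherwise).
    """
    n = dend.n_leaves
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}]")
    # cut_tree undoes exactly the k-1 largest merges, so ties at equal
    # heights still yield exactly k clusters
    raw = hierarchy.cut_tree(dend.linkage, n_clusters=k).ravel()
    uniq = np.unique(raw)
    if dend.frequencies is not None:
        order = np.argsort(
            [np.median(dend.frequencies[raw == u]) for u in uniq],
            kind="stable",
        )
    else:
        order = np.argsort(
            [np.flatnonzero(raw == u)[0] for u in uniq], kind="stable"
        )
    relabel = {int(uniq[o]): i for i, o in enumerate(order)}
    return np.array([relabel[int(r)] for r in raw])
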