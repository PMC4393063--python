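"""Two-step cluster validation and dynamic-membership summaries.

Step one selects the number of clusters: the observed merge-distance
profile d_k is compared against the 95th-percentile profile d_k* of
Monte-Carlo reference datasets whose component frequencies are drawn
uniformly over the convex hull of the observed frequencies (for 1-D
frequencies, the interval [min, max]); the selected k0 is the largest k
with d_k > d_k*, i.e. the last merge that is significantly more
expensive than chance, falling back to a single cluster when no merge
is.

Step two separates significant clusters from noise: each observed
cluster's average silhouette width is referred to the pooled
distribution of average silhouettes from M uniform-null datasets cut at
the same k0, with an add-one permutation-style P-value; clusters with
P >= alpha are flagged as noise.

Because member components carry individual time supports, the gene
count of a cluster varies over time; a nonparametric bootstrap over
genes gives a pointwise 95% confidence band for that membership curve.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.metrics import silhouette_samples

from .cluster import (Dendrogram, MergeDistanceProfile, cut, merge_profile,
                      ward_cluster, ward_linkage_from_dissimilarity)
from .decompose import Component
from .params import SimilarityParams, ValidationParams
from .similarity import (SimilarityMatrix, _coco_values,
                         similarity_from_frequencies)

__all__ = [
    "NullThresholdCurve",
    "ClusterStats",
    "ClusterResult",
    "MembershipCurve",
    "null_merge_thresholds",
    "select_k",
    "silhouettes",
    "cluster_significance",
    "membership_curve",
]


@dataclass(frozen=True)
class NullThresholdCurve:
    """95th-percentile null merge heights d_k*, k = 2..n."""

    ks: np.ndarray
    thresholds: np.ndarray
    n_replicates: int
    seed: int

    def __post_init__(self):
        if self.ks.shape != self.thresholds.shape:
            raise ValueError("ks and thresholds must be congruent")
        if np.any(self.thresholds < 0):
            raise ValueError("null thresholds must be non-negative")


@dataclass(frozen=True)
class ClusterStats:
    cluster_id: int
    n_components: int
    n_genes: int
    representative_frequency: float  # median member frequency, Hz
    average_silhouette: float
    p_value: float
    significant: bool


@dataclass
class ClusterResult:
    """Selected clustering with per-cluster significance."""

    k0: int
    labels: np.ndarray  # per component, 0..k0-1
    components: Tuple[Component, ...]
    clusters: Tuple[ClusterStats, ...]
    alpha: float

    def __post_init__(self):
        for c in self.clusters:
            if not 0.0 <= c.p_value <= 1.0:
                raise ValueError("P-values must lie in [0, 1]")

    @property
    def significant_clusters(self) -> Tuple[ClusterStats, ...]:
        return tuple(c for c in self.clusters if c.significant)

    @property
    def noise_cluster_ids(self) -> Tuple[int, ...]:
        return tuple(c.cluster_id for c in self.clusters if not c.significant)

    def members(self, cluster_id: int) -> List[Component]:
        return [
            c for c, l in zip(self.components, self.labels) if l == cluster_id
        ]

    def to_frame(self) -> pd.DataFrame:
        stats = {c.cluster_id: c for c in self.clusters}
        rows = []
        for comp, lab in zip(self.components, self.labels):
            s = stats[int(lab)]
            rows.append(
                {
                    "gene_id": comp.gene_id,
                    "cluster_id": int(lab),
                    "frequency_hz": comp.frequency,
                    "start_time_s": comp.start_time,
                    "end_time_s": comp.end_time,
                    "cluster_p_value": s.p_value,
                    "significant": s.significant,
                }
            )
        return pd.DataFrame(rows)

    def write(self, prefix: str) -> None:
        self.to_frame().to_csv(f"{prefix}.components.tsv", sep="\t", index=False)
        summary = {
            "k0": int(self.k0),
            "alpha": self.alpha,
            "clusters": [
                {
                    "cluster_id": c.cluster_id,
                    "n_components": c.n_components,
                    "n_genes": c.n_genes,
                    "representative_frequency_hz": c.representative_frequency,
                    "average_silhouette": c.average_silhouette,
                    "p_value": c.p_value,
                    "significant": c.significant,
                }
                for c in self.clusters
            ],
        }
        with open(f"{prefix}.clusters.json", "w") as fh:
            json.dump(summary, fh, indent=1)


@dataclass(frozen=True)
class MembershipCurve:
    """Gene counts over time per significant cluster with a bootstrap
    95% band."""

    timepoints: np.ndarray
    cluster_ids: Tuple[int, ...]
    counts: np.ndarray  # (n_clusters, n_time) int
    lower: np.ndarray
    upper: np.ndarray
    n_bootstrap: int

    def to_frame(self) -> pd.DataFrame:
        cols: Dict[str, np.ndarray] = {"time": self.timepoints}
        for i, cid in enumerate(self.cluster_ids):
            cols[f"cluster{cid}_count"] = self.counts[i]
            cols[f"cluster{cid}_lo"] = self.lower[i]
            cols[f"cluster{cid}_hi"] = self.upper[i]
        return pd.DataFrame(cols)

    def write(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# null reference machinery


def _null_profiles(
    frequencies: np.ndarray,
    M: int,
    seed: int,
    sampling_rate: float,
    uniform_length: int,
    sim_params: SimilarityParams,
    k0: Optional[int] = None,
) -> Tuple[np.ndarray, Optional[List[np.ndarray]]]:
    """Merge-height profiles (and, if ``k0`` is given, per-replicate
    cluster-average silhouettes at the k0 cut) for M uniform-hull
    reference datasets."""
    f = np.asarray(frequencies, dtype=float)
    lo, hi = float(f.min()), float(f.max())
    if hi <= lo:
        raise ValueError(
            "all observed frequencies are identical; the uniform hull is "
            "degenerate and clustering is vacuous"
        )
    n = len(f)
    rng = np.random.default_rng(seed)
    heights = np.empty((M, n - 1))
    sils: Optional[List[np.ndarray]] = [] if k0 is not None else None
    for rep in range(M):
        draw = rng.uniform(lo, hi, size=n)
        values, _ = _coco_values(draw, sampling_rate, uniform_length, sim_params)
        d = 1.0 - values
        np.fill_diagonal(d, 0.0)
        Z = ward_linkage_from_dissimilarity(d)
        heights[rep] = np.sort(Z[:, 2])
        if sils is not None:
            from scipy.cluster import hierarchy

            labels = hierarchy.cut_tree(Z, n_clusters=k0).ravel()
            if len(np.unique(labels)) < 2:
                sils.append(np.zeros(1))
                continue
            s = silhouette_samples(d, labels, metric="precomputed")
            sils.append(
                np.array([s[labels == u].mean() for u in np.unique(labels)])
            )
    return heights, sils


def null_merge_thresholds(
    frequencies: Sequence[float],
    M: int = 1000,
    percentile: float = 95.0,
    seed: int = 0,
    sampling_rate: float = 6.3,
    uniform_length: int = 64,
    sim_params: SimilarityParams = SimilarityParams(),
) -> NullThresholdCurve:
    """Null merge-height curve d_k* from M uniform draws on the
    frequency hull [min, max]."""
    if M < 1:
        raise ValueError("M must be at least 1")
    n = len(frequencies)
    if n < 2:
        raise ValueError("need at least two components")
    heights, _ = _null_profiles(
        np.asarray(frequencies), M, seed, sampling_rate, uniform_length,
        sim_params,
    )
    ks = np.arange(2, n + 1)
    # ascending-height merge number n-k+1 -> column n-k
    cols = n - ks
    thresholds = np.percentile(heights[:, cols], percentile, axis=0)
    return NullThresholdCurve(
        ks=ks, thresholds=thresholds, n_replicates=M, seed=seed
    )


def select_k(
    observed: MergeDistanceProfile, null: NullThresholdCurve
) -> int:
    """Largest k whose observed merge height exceeds the null
    threshold; 1 if no merge does."""
    if not np.array_equal(observed.ks, null.ks):
        raise ValueError("observed and null profiles index different k")
    # tolerance keeps numerically-zero merges (duplicate frequencies on
    # both sides) from registering as exceedances
    scale = max(observed.heights.max(), null.thresholds.max(), 1.0)
    exceeds = observed.heights > null.thresholds + 1e-6 * scale
    if not exceeds.any():
        return 1
    return int(observed.ks[exceeds].max())


def silhouettes(
    labels: Sequence[int], dissimilarity: np.ndarray
) -> Tuple[np.ndarray, Dict[int, float]]:
    """Silhouette width s(i) = (b - a) / max(a, b) per object and the
    per-cluster averages; singleton clusters score 0."""
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValueError(
            "silhouettes need at least two clusters (b(i) is undefined)"
        )
    s = silhouette_samples(dissimilarity, labels, metric="precomputed")
    return s, {int(u): float(s[labels == u].mean()) for u in uniq}


def cluster_significance(
    components: Sequence[Component],
    labels: Sequence[int],
    sim: SimilarityMatrix,
    k0: int,
    sampling_rate: float,
    uniform_length: int,
    val_params: ValidationParams = ValidationParams(),
    sim_params: SimilarityParams = SimilarityParams(),
    seed: int = 0,
) -> ClusterResult:
    """Silhouette-based significance of each of the k0 clusters.

    M uniform-hull reference datasets are clustered and cut at k0; the
    pooled M*k0 null cluster-average silhouettes form the reference
    distribution, and each observed cluster gets the add-one P-value
    ``(1 + #{null >= observed}) / (n_null + 1)``.
    """
    labels = np.asarray(labels)
    components = tuple(components)
    freqs = np.array([c.frequency for c in components])
    gene_of = np.array([c.gene_id for c in components])

    def stats_for(
        cid: int, avg_sil: float, p: float
    ) -> ClusterStats:
        m = labels == cid
        return ClusterStats(
            cluster_id=int(cid),
            n_components=int(m.sum()),
            n_genes=len(set(gene_of[m])),
            representative_frequency=float(np.median(freqs[m])),
            average_silhouette=avg_sil,
            p_value=p,
            significant=p < val_params.alpha,
        )

    if k0 < 2:
        # a single cluster cannot be tested against separation nulls
        return ClusterResult(
            k0=1,
            labels=np.zeros(len(components), dtype=int),
            components=components,
            clusters=(stats_for(0, 0.0, 1.0),),
            alpha=val_params.alpha,
        )

    d = sim.dissimilarity()
    _, observed_avgs = silhouettes(labels, d)
    _, null_sils = _null_profiles(
        freqs,
        val_params.n_replicates,
        seed,
        sampling_rate,
        uniform_length,
        sim_params,
        k0=k0,
    )
    pool = np.concatenate(null_sils)
    stats = []
    for cid in sorted(observed_avgs):
        obs = observed_avgs[cid]
        p = (1.0 + np.sum(pool >= obs)) / (len(pool) + 1.0)
        stats.append(stats_for(cid, obs, float(p)))
    return ClusterResult(
        k0=k0,
        labels=labels,
        components=components,
        clusters=tuple(stats),
        alpha=val_params.alpha,
    )


def membership_curve(
    clusters: ClusterResult,
    timepoints: np.ndarray,
    B: int = 1000,
    seed: int = 0,
    significant_only: bool = True,
) -> MembershipCurve:
    """Gene count per cluster at each time point with a bootstrap band.

    A gene is in cluster c at time t if it has a member component whose
    [start, end] support covers t.  Genes are resampled with
    replacement B times and the 2.5/97.5 percentiles of the recounted
    curves form the pointwise 95% band.
    """
    if B < 1:
        raise ValueError("B must be at least 1")
    rng = np.random.default_rng(seed)
    cids = [
        c.cluster_id
        for c in clusters.clusters
        if c.significant or not significant_only
    ]
    if not cids:
        cids = [c.cluster_id for c in clusters.clusters]
    t = np.asarray(timepoints, dtype=float)
    counts = np.zeros((len(cids), len(t)), dtype=int)
    lower = np.zeros_like(counts)
    upper = np.zeros_like(counts)
    for i, cid in enumerate(cids):
        members = clusters.members(cid)
        genes = sorted({c.gene_id for c in members})
        # per-gene coverage mask over time
        cover = np.zeros((len(genes), len(t)), dtype=bool)
        gidx = {g: j for j, g in enumerate(genes)}
        for comp in members:
            cover[gidx[comp.gene_id]] |= (t >= comp.start_time) & (
                t <= comp.end_time
            )
        counts[i] = cover.sum(axis=0)
        if len(genes) == 0:
            continue
        idx = rng.integers(0, len(genes), size=(B, len(genes)))
        boot = cover[idx].sum(axis=1)  # (B, n_time)
        lower[i] = np.percentile(boot, 2.5, axis=0)
        upper[i] = np.percentile(boot, 97.5, axis=0)
    return MembershipCurve(
        timepoints=t,
        cluster_ids=tuple(cids),
        counts=counts,
        lower=lower,
        upper=upper,
        n_bootstrap=B,
    )
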