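"""Truth-based evaluation: decomposition power and the discovery index.

When the generating truth of a simulated dataset is known, two scores
quantify the two halves of the pipeline.

Decomposition power compares the true and estimated components of one
gene as a time-coverage Jaccard: ``sum(w) / (sum(u) + sum(v) - sum(w))``
where u are true durations, v estimated durations and w the durations
of the true/estimated overlaps (components paired by frequency
proximity).

The discovery index scores the full pipeline.  Each true class (a
frequency with its member genes and their true time intervals) is
matched to the nearest estimated cluster by representative frequency
under a small cutoff; for gene g in matched pair j the index is the
interval Jaccard ``D_gj = |P_gj n Q_gj| / |P_gj u Q_gj|`` of the true
interval P and the estimated interval Q (union of the gene's member-
component supports in the cluster); genes present on only one side
score 0, as do all genes of unmatched classes and superfluous
clusters.  The overall index is ``D = sum_j sum_g D_gj / sum_j O_j``
with O_j the gene count of the class (or, for a superfluous cluster,
of that cluster), so D lives in [0, 1].
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import product
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .decompose import Component, decompose
from .params import PipelineParams
from .synthetic import SimulatedDataset, TwoComponentConfig, simulate_two_component
from .validate import ClusterResult

__all__ = [
    "TruthAssignment",
    "ClassClusterMatching",
    "DiscoveryReport",
    "decomposition_power",
    "match_classes",
    "discovery_index",
    "power_study",
]

Interval = Tuple[float, float]


def _union_length(intervals: Sequence[Interval]) -> float:
    if not intervals:
        return 0.0
    ivs = sorted(intervals)
    total, (lo, hi) = 0.0, ivs[0]
    for a, b in ivs[1:]:
        if a > hi:
            total += hi - lo
            lo, hi = a, b
        else:
            hi = max(hi, b)
    return total + (hi - lo)


def _intersection_length(xs: Sequence[Interval], ys: Sequence[Interval]) -> float:
    return sum(
        max(0.0, min(bx, by) - max(ax, ay))
        for (ax, bx), (ay, by) in product(xs, ys)
    )


@dataclass(frozen=True)
class TruthAssignment:
    """True classes: frequency -> {gene -> true time interval}."""

    classes: Dict[float, Dict[str, Interval]]

    def __post_init__(self):
        for f, members in self.classes.items():
            if not members:
                raise ValueError(f"class {f:g} Hz has no genes")
            for g, (a, b) in members.items():
                if not a < b:
                    raise ValueError(f"empty interval for gene {g!r}")

    @classmethod
    def from_dataset(cls, dataset: SimulatedDataset) -> "TruthAssignment":
        classes: Dict[float, Dict[str, Interval]] = {}
        for gene, comps in dataset.truth.items():
            for f, a, b in comps:
                classes.setdefault(f, {})[gene] = (a, b)
        return cls(classes=classes)

    @property
    def frequencies(self) -> List[float]:
        return sorted(self.classes)


@dataclass(frozen=True)
class ClassClusterMatching:
    """One-to-one class-to-cluster assignment by frequency proximity."""

    pairs: Dict[float, int]  # class frequency -> cluster id
    unmatched_classes: Tuple[float, ...]
    superfluous_clusters: Tuple[int, ...]
    cutoff: float


@dataclass(frozen=True)
class DiscoveryReport:
    overall: float
    per_gene: pd.DataFrame  # columns: class_frequency, gene_id, d
    matching: ClassClusterMatching
    n_genes: int
    o_j: Dict[str, int]  # per enumerated class/cluster gene count

    def __post_init__(self):
        if not 0.0 <= self.overall <= 1.0:
            raise ValueError("overall discovery index must lie in [0, 1]")

    def write(self, path) -> None:
        payload = {
            "overall_discovery_index": self.overall,
            "n_genes": self.n_genes,
            "o_j": self.o_j,
            "matched": {f"{k:g}": int(v) for k, v in self.matching.pairs.items()},
            "unmatched_classes": list(self.matching.unmatched_classes),
            "superfluous_clusters": list(self.matching.superfluous_clusters),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def decomposition_power(
    true_components: Sequence[Tuple[float, float, float]],
    estimated_components: Sequence[Component],
    freq_tol_octaves: float = 0.25,
) -> float:
    """Time-coverage Jaccard between true and estimated components of
    one gene.

    ``true_components`` are (frequency, start, end) triples.  Each
    estimated component is paired with the closest true frequency (on a
    log scale); the pair overlaps only if the frequencies agree within
    ``freq_tol_octaves`` octaves, roughly the analysis grid width.
    """
    if not true_components:
        raise ValueError("power is undefined without true components")
    u = sum(b - a for _, a, b in true_components)
    v = sum(c.duration for c in estimated_components)
    w = 0.0
    for c in estimated_components:
        dists = [
            abs(np.log2(c.frequency / f)) for f, _, _ in true_components
        ]
        i = int(np.argmin(dists))
        if dists[i] <= freq_tol_octaves:
            f, a, b = true_components[i]
            w += max(0.0, min(b, c.end_time) - max(a, c.start_time))
    w = min(w, u, v)
    denom = u + v - w
    return float(w / denom) if denom > 0 else 0.0


def match_classes(
    classes: TruthAssignment,
    clusters: ClusterResult,
    cutoff: float = 0.1,
    significant_only: bool = True,
) -> ClassClusterMatching:
    """Greedily match each class to its nearest cluster by
    |frequency difference|, one-to-one, accepting only distances below
    ``cutoff`` (Hz).  Noise clusters are excluded by default — the
    validation step has already declared them unstructured."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    stats = [
        c
        for c in clusters.clusters
        if c.significant or not significant_only
    ]
    cands = sorted(
        (
            (abs(cf - s.representative_frequency), cf, s.cluster_id)
            for cf in classes.frequencies
            for s in stats
        ),
    )
    pairs: Dict[float, int] = {}
    used: set = set()
    for dist, cf, cid in cands:
        if dist >= cutoff or cf in pairs or cid in used:
            continue
        pairs[cf] = cid
        used.add(cid)
    unmatched = tuple(f for f in classes.frequencies if f not in pairs)
    superfluous = tuple(
        s.cluster_id for s in stats if s.cluster_id not in used
    )
    return ClassClusterMatching(
        pairs=pairs,
        unmatched_classes=unmatched,
        superfluous_clusters=superfluous,
        cutoff=cutoff,
    )


def discovery_index(
    classes: TruthAssignment,
    clusters: ClusterResult,
    matching: Optional[ClassClusterMatching] = None,
    cutoff: float = 0.1,
) -> DiscoveryReport:
    """Overall and per-gene discovery indices for a clustering against
    the generating truth."""
    if matching is None:
        matching = match_classes(classes, clusters, cutoff=cutoff)
    rows: List[dict] = []
    o_j: Dict[str, int] = {}
    numerator = 0.0
    genes_seen: set = set()
    for cf in classes.frequencies:
        members = classes.classes[cf]
        o_j[f"class_{cf:g}"] = len(members)
        genes_seen.update(members)
        cid = matching.pairs.get(cf)
        cluster_supports: Dict[str, List[Interval]] = {}
        if cid is not None:
            for comp in clusters.members(cid):
                cluster_supports.setdefault(comp.gene_id, []).append(
                    (comp.start_time, comp.end_time)
                )
        for gene in sorted(set(members) | set(cluster_supports)):
            p = members.get(gene)
            q = cluster_supports.get(gene, [])
            if p is None or not q:
                d = 0.0
            else:
                inter = _intersection_length([p], q)
                union = _union_length([p] + q)
                d = inter / union if union > 0 else 0.0
            numerator += d
            rows.append(
                {"class_frequency": cf, "gene_id": gene, "d": d}
            )
    for cid in matching.superfluous_clusters:
        members = {c.gene_id for c in clusters.members(cid)}
        o_j[f"cluster_{cid}"] = len(members)
        for gene in sorted(members):
            rows.append(
                {"class_frequency": np.nan, "gene_id": gene, "d": 0.0}
            )
    denom = sum(o_j.values())
    overall = numerator / denom if denom > 0 else 0.0
    return DiscoveryReport(
        overall=float(overall),
        per_gene=pd.DataFrame(rows),
        matching=matching,
        n_genes=len(genes_seen),
        o_j=o_j,
    )


def power_study(
    base_frequencies: Sequence[float],
    delta_frequencies: Sequence[float],
    amplitude_ratio: float = 1.0,
    noise_level: float = 0.0,
    replicates: int = 100,
    seed: int = 0,
    params: Optional[PipelineParams] = None,
) -> pd.DataFrame:
    """Mean decomposition power over a (f, delta_f) grid of
    two-component signals.

    Each cell simulates ``replicates`` signals (random phases, additive
    noise) and averages the per-signal power against the known truth
    (two full-record components).  Returns a tidy frame with columns
    f, delta_f, mean_power, n.
    """
    if replicates < 1:
        raise ValueError("replicates must be at least 1")
    if params is None:
        params = PipelineParams.fast()
    root = np.random.SeedSequence(seed)
    noise_seed = int(root.generate_state(1)[0] >> 1) % (2**31)
    rows = []
    for f in base_frequencies:
        for df in delta_frequencies:
            streams = np.random.SeedSequence([seed, int(f * 1e6), int(df * 1e6)])
            child = streams.generate_state(2 * replicates) >> 1
            powers = []
            for r in range(replicates):
                cfg = TwoComponentConfig(
                    base_frequency=f,
                    delta_frequency=df,
                    amplitude_ratio=amplitude_ratio,
                    noise_level=noise_level,
                    seed=int(child[2 * r]) % (2**31),
                )
                series = simulate_two_component(cfg)
                est = decompose(
                    series,
                    params,
                    seed=int(child[2 * r + 1]) % (2**31),
                    noise_seed=noise_seed,
                )
                truth = [
                    (f, cfg.t_start, cfg.t_end),
                    (f + df, cfg.t_start, cfg.t_end),
                ]
                powers.append(decomposition_power(truth, est))
            rows.append(
                {
                    "f": f,
                    "delta_f": df,
                    "mean_power": float(np.mean(powers)),
                    "n": replicates,
                }
            )
    return pd.DataFrame(rows)
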