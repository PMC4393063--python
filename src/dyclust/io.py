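"""Reading, writing, imputation, and the end-to-end pipeline.

Expression matrices are gene-by-time TSV/CSV files with a header of
time labels; time labels are converted to seconds internally (periods
are reported back in the input unit).  Missing values are imputed by
k-nearest-neighbour averaging over genes before decomposition, since
the wavelet transform requires complete, evenly sampled series.

:func:`run_pipeline` composes the whole analysis — impute, decompose
every gene, pool components, CoCo similarity, Ward clustering,
cluster-number selection, silhouette significance, membership curves,
and (when truth is available) the discovery index — as a pure function
of ``(data, params, seed)``.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from sklearn.impute import KNNImputer

from .cluster import Dendrogram, MergeDistanceProfile, cut, merge_profile, ward_cluster
from .decompose import Component, decompose
from .evaluate import DiscoveryReport, TruthAssignment, discovery_index
from .params import PipelineParams
from .similarity import SimilarityMatrix, _uniform_length, similarity_matrix
from .synthetic import ExpressionSeries, SimulatedDataset
from .validate import (ClusterResult, MembershipCurve, NullThresholdCurve,
                       cluster_significance, membership_curve,
                       null_merge_thresholds, select_k)

__all__ = [
    "ExpressionMatrix",
    "read_expression",
    "knn_impute",
    "write_components",
    "read_components",
    "run_pipeline",
    "PipelineResult",
]

_TIME_UNIT_SECONDS = {"s": 1.0, "sec": 1.0, "seconds": 1.0,
                      "min": 60.0, "h": 3600.0, "hours": 3600.0}


@dataclass
class ExpressionMatrix:
    """Gene-by-time expression values with a missing-value mask."""

    values: pd.DataFrame  # index gene ids, columns time labels (input unit)
    time_unit: str = "s"

    def __post_init__(self):
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()]
            raise ValueError(f"duplicate gene ids: {list(dups[:5])}")
        if self.time_unit not in _TIME_UNIT_SECONDS:
            raise ValueError(f"unknown time unit {self.time_unit!r}")
        t = self.time_labels
        if np.any(np.diff(t) <= 0):
            raise ValueError("time labels must be strictly increasing")

    @property
    def time_labels(self) -> np.ndarray:
        return np.array([float(c) for c in self.values.columns])

    @property
    def timepoints_seconds(self) -> np.ndarray:
        return self.time_labels * _TIME_UNIT_SECONDS[self.time_unit]

    @property
    def missing_mask(self) -> np.ndarray:
        return self.values.isna().to_numpy()

    @property
    def fully_missing_columns(self) -> np.ndarray:
        """Indices of time points with no observed value for any gene."""
        return np.flatnonzero(self.values.isna().all(axis=0).to_numpy())

    def is_evenly_spaced(self, rtol: float = 1e-4) -> bool:
        d = np.diff(self.time_labels)
        return bool(np.allclose(d, d[0], rtol=rtol))

    def to_series(self) -> List[ExpressionSeries]:
        if self.missing_mask.any():
            raise ValueError("matrix contains missing values; impute first")
        if not self.is_evenly_spaced():
            raise ValueError("time labels are unevenly spaced")
        ts = self.timepoints_seconds
        # regularize label round-off onto an exact grid
        t = np.linspace(ts[0], ts[-1], len(ts))
        return [
            ExpressionSeries(str(g), row.to_numpy(dtype=float), t)
            for g, row in self.values.iterrows()
        ]

    def write(self, path) -> None:
        sep = "," if str(path).endswith(".csv") else "\t"
        self.values.to_csv(path, sep=sep)


def read_expression(path, time_unit: str = "s") -> ExpressionMatrix:
    """Parse a gene-by-time TSV/CSV; empty cells and NA tokens become
    missing values."""
    sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0)
    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()
                          & df[col].notna()]
            if len(bad):
                raise ValueError(
                    f"non-numeric cell(s) in column {col!r}: "
                    f"{bad.iloc[0]!r} (gene {bad.index[0]!r})"
                )
            df[col] = pd.to_numeric(df[col], errors="coerce")
    return ExpressionMatrix(values=df, time_unit=time_unit)


def knn_impute(matrix: ExpressionMatrix, k: int = 12,
               weights: str = "distance") -> ExpressionMatrix:
    """Fill missing cells from the k nearest genes.

    Distances are Euclidean over mutually observed time points and the
    neighbours' values are averaged with inverse-distance weights (set
    ``weights="uniform"`` for a plain mean).  Time points missing for
    every gene carry no neighbour information at all, so they are first
    filled per gene by linear interpolation along time.
    """
    if k < 1:
        raise ValueError("k must be at least 1")
    df = matrix.values.copy()
    all_missing = df.isna().all(axis=1)
    if all_missing.any():
        raise ValueError(
            f"gene(s) missing everywhere: {list(df.index[all_missing][:5])}"
        )
    if not df.isna().any().any():
        return ExpressionMatrix(values=df, time_unit=matrix.time_unit)
    cols = matrix.fully_missing_columns
    if cols.size:
        t = matrix.time_labels
        vals = df.to_numpy(dtype=float)
        for i in range(vals.shape[0]):
            obs = ~np.isnan(vals[i])
            vals[i, cols] = np.interp(t[cols], t[obs], vals[i, obs])
        df = pd.DataFrame(vals, index=df.index, columns=df.columns)
    imputer = KNNImputer(n_neighbors=k, weights=weights)
    filled = imputer.fit_transform(df.to_numpy(dtype=float))
    out = pd.DataFrame(filled, index=df.index, columns=df.columns)
    return ExpressionMatrix(values=out, time_unit=matrix.time_unit)


# ---------------------------------------------------------------------------
# component round-trip


def write_components(components: Sequence[Component], path) -> None:
    pd.DataFrame(
        [
            {
                "gene_id": c.gene_id,
                "frequency_hz": c.frequency,
                "start_time_s": c.start_time,
                "end_time_s": c.end_time,
                "strength": c.mean_excess_modulus,
                "phase_rad": np.nan if c.phase is None else c.phase,
            }
            for c in components
        ]
    ).to_csv(path, sep="\t", index=False)


def read_components(path) -> List[Component]:
    df = pd.read_csv(path, sep="\t")
    return [
        Component(
            gene_id=str(r.gene_id),
            frequency=float(r.frequency_hz),
            start_time=float(r.start_time_s),
            end_time=float(r.end_time_s),
            mean_excess_modulus=float(r.strength),
            phase=None if pd.isna(r.phase_rad) else float(r.phase_rad),
        )
        for r in df.itertuples()
    ]


# ---------------------------------------------------------------------------
# end-to-end pipeline


@dataclass
class PipelineResult:
    components: List[Component]
    similarity: SimilarityMatrix
    dendrogram: Dendrogram
    profile: MergeDistanceProfile
    null_curve: NullThresholdCurve
    clusters: ClusterResult
    membership: MembershipCurve
    discovery: Optional[DiscoveryReport]
    log: Dict

    def write(self, outdir) -> None:
        os.makedirs(outdir, exist_ok=True)
        join = lambda name: os.path.join(outdir, name)
        write_components(self.components, join("components.tsv"))
        self.similarity.write(join("similarity.tsv"))
        np.savetxt(
            join("linkage.txt"),
            self.dendrogram.linkage,
            header="child_a\tchild_b\theight\tsize",
            delimiter="\t",
        )
        with open(join("tree.nwk"), "w") as fh:
            fh.write(self.dendrogram.to_newick() + "\n")
        self.clusters.write(join("result"))
        self.membership.write(join("membership.tsv"))
        if self.discovery is not None:
            self.discovery.write(join("discovery.json"))
            self.discovery.per_gene.to_csv(
                join("discovery_per_gene.tsv"), sep="\t", index=False
            )
        with open(join("log.json"), "w") as fh:
            json.dump(self.log, fh, indent=1)


def run_pipeline(
    data: Union[ExpressionMatrix, SimulatedDataset, Sequence[ExpressionSeries]],
    params: Optional[PipelineParams] = None,
    seed: int = 0,
    truth: Optional[TruthAssignment] = None,
    impute_k: int = 12,
) -> PipelineResult:
    """Run the full dynamic-clustering analysis.

    ``data`` may be an :class:`ExpressionMatrix` (imputed if needed), a
    :class:`SimulatedDataset` (its truth is used automatically), or a
    list of series.  The run is fully reproducible under
    ``(data, params, seed)``.
    """
    if params is None:
        params = PipelineParams()
    if isinstance(data, SimulatedDataset):
        series = data.series
        if truth is None:
            truth = TruthAssignment.from_dataset(data)
    elif isinstance(data, ExpressionMatrix):
        if data.missing_mask.any():
            data = knn_impute(data, k=impute_k)
        series = data.to_series()
    else:
        series = list(data)
    if not series:
        raise ValueError("no series to analyse")

    root = np.random.SeedSequence(seed)
    noise_seed, null_seed, sig_seed, boot_seed = (
        int(s) % (2**31) for s in root.generate_state(4) >> 1
    )
    gene_seeds = root.spawn(len(series))

    components: List[Component] = []
    for s, gss in zip(series, gene_seeds):
        components.extend(
            decompose(
                s,
                params,
                seed=int(gss.generate_state(1)[0] >> 1) % (2**31),
                noise_seed=noise_seed,
            )
        )
    if len(components) < 2:
        raise ValueError(
            f"only {len(components)} significant component(s) extracted; "
            "nothing to cluster"
        )
    fs = series[0].sampling_rate
    uniform_length = _uniform_length(components, fs)
    sim = similarity_matrix(
        components, fs, params.similarity, uniform_length=uniform_length
    )
    dend = ward_cluster(sim)
    profile = merge_profile(dend)
    freqs = [c.frequency for c in components]
    null_curve = null_merge_thresholds(
        freqs,
        M=params.validation.n_replicates,
        percentile=params.validation.percentile,
        seed=null_seed,
        sampling_rate=fs,
        uniform_length=uniform_length,
        sim_params=params.similarity,
    )
    k0 = select_k(profile, null_curve)
    labels = cut(dend, k0)
    clusters = cluster_significance(
        components,
        labels,
        sim,
        k0,
        sampling_rate=fs,
        uniform_length=uniform_length,
        val_params=params.validation,
        sim_params=params.similarity,
        seed=sig_seed,
    )
    membership = membership_curve(
        clusters,
        series[0].timepoints,
        B=params.validation.n_bootstrap,
        seed=boot_seed,
    )
    discovery = None
    if truth is not None:
        discovery = discovery_index(truth, clusters)

    cfg_hash = hashlib.sha256(repr(params).encode()).hexdigest()[:12]
    log = {
        "seed": seed,
        "config_sha256_12": cfg_hash,
        "n_series": len(series),
        "n_components": len(components),
        "uniform_length": uniform_length,
        "k0": int(k0),
        "n_significant": len(clusters.significant_clusters),
    }
    return PipelineResult(
        components=components,
        similarity=sim,
        dendrogram=dend,
        profile=profile,
        null_curve=null_curve,
        clusters=clusters,
        membership=membership,
        discovery=discovery,
        log=log,
    )
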