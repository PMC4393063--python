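"""Replicated simulation experiments.

These drive the package's benchmark studies: the discovery index of the
full pipeline on the three-group design across noise levels, and
structure recovery on the time-varying design.  Both are deterministic
functions of their seed.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .io import run_pipeline
from .params import PipelineParams
from .synthetic import GroupDesign, simulate_group_dataset

__all__ = ["discovery_noise_study", "dynamic_structure_study"]


def _child_seed(*key: int) -> int:
    return int(np.random.SeedSequence(list(key)).generate_state(1)[0] >> 1)


def discovery_noise_study(
    noise_levels: Sequence[float] = (0.5, 1.0, 1.5),
    replicates: int = 50,
    seed: int = 0,
    params: Optional[PipelineParams] = None,
) -> pd.DataFrame:
    """Mean overall discovery index of the full pipeline on the
    three-group design (20/40/80 genes at 0.1/0.4/0.8 Hz, 64 points on
    [0, 10] s) at each noise level.

    Returns one row per (noise_level, replicate) with the overall
    discovery index, the selected cluster count and the number of
    significant clusters.
    """
    if params is None:
        params = PipelineParams.fast()
    rows = []
    for li, noise in enumerate(noise_levels):
        for rep in range(replicates):
            ds = simulate_group_dataset(
                GroupDesign.three_group(noise),
                seed=_child_seed(seed, 11, li, rep),
            )
            res = run_pipeline(
                ds, params, seed=_child_seed(seed, 13, li, rep)
            )
            rows.append(
                {
                    "noise_level": noise,
                    "replicate": rep,
                    "discovery_index": res.discovery.overall,
                    "k0": res.clusters.k0,
                    "n_significant": len(res.clusters.significant_clusters),
                }
            )
    return pd.DataFrame(rows)


def dynamic_structure_study(
    runs: int = 20,
    noise_sd: float = 0.5,
    seed: int = 0,
    params: Optional[PipelineParams] = None,
) -> pd.DataFrame:
    """Structure recovery on the time-varying three-group design.

    Per run: the number of significant clusters, their representative
    frequencies, the median member frequency of the highest-frequency
    significant cluster, and whether that cluster's group-2 gene count
    drops — and its group-1 count rises — across the t = 5 s change
    point, as the design dictates.
    """
    if params is None:
        params = PipelineParams.fast()
    rows = []
    for r in range(runs):
        ds = simulate_group_dataset(
            GroupDesign.three_group_dynamic(noise_sd),
            seed=_child_seed(seed, 21, r),
        )
        res = run_pipeline(ds, params, seed=_child_seed(seed, 23, r))
        sig = res.clusters.significant_clusters
        freqs = sorted(c.representative_frequency for c in sig)
        row = {
            "run": r,
            "k0": res.clusters.k0,
            "n_significant": len(sig),
            "frequencies": freqs,
            "high_cluster_frequency": np.nan,
            "g2_drops": False,
            "g1_rises": False,
        }
        if sig:
            hi = max(sig, key=lambda c: c.representative_frequency)
            members = res.clusters.members(hi.cluster_id)
            row["high_cluster_frequency"] = float(
                np.median([c.frequency for c in members])
            )
            t = ds.series[0].timepoints

            def group_counts(prefix):
                cover = np.zeros_like(t)
                for c in members:
                    if c.gene_id.startswith(prefix):
                        cover += (t >= c.start_time) & (t <= c.end_time)
                return cover

            g1, g2 = group_counts("g1"), group_counts("g2")
            row["g2_drops"] = g2[t < 5].mean() > g2[t > 5].mean()
            row["g1_rises"] = g1[t > 5].mean() > g1[t < 5].mean()
        rows.append(row)
    return pd.DataFrame(rows)
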