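"""Tunable parameters for the dynamic-clustering pipeline.

Every stage of the pipeline (wavelet decomposition, ridge extraction,
coherency similarity, cluster validation) reads its knobs from one
:class:`PipelineParams` object so that a run is a pure function of
``(data, params, seed)``.  Defaults are the recommended analysis
settings; :meth:`PipelineParams.fast` lowers the Monte-Carlo sizes for
quick exploratory runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import yaml


@dataclass(frozen=True)
class WaveletParams:
    """Morlet CWT settings.

    omega0
        Center frequency of the Morlet mother wavelet (rad).  6.0 is the
        standard compromise between admissibility and time-frequency
        resolution.
    voices
        Number of log-spaced scales per octave.
    f_min, f_max
        Frequency band analysed, in Hz.  ``None`` means data-driven:
        half a cycle per record (0.5/T) up to the Nyquist frequency
        (components are only reported from one cycle per record up).
    padding
        Boundary handling: ``"periodic"`` (circular extension, exact
        for signals with whole cycles in the record — the case this
        method targets) or ``"reflect"`` (symmetric reflection, safer
        for aperiodic trends but it aliases a one-cycle sinusoid at
        quarter phase to 1.5 cycles).
    """

    omega0: float = 6.0
    voices: int = 12
    f_min: Optional[float] = None
    f_max: Optional[float] = None
    padding: str = "periodic"


@dataclass(frozen=True)
class ThresholdParams:
    """White-noise threshold-surface settings.

    n_replicates
        Number of white-noise series whose CWT moduli build the
        empirical percentile surface (M).
    percentile
        Percentile of the M moduli used as the significance threshold.
    """

    n_replicates: int = 1000
    percentile: float = 95.0


@dataclass(frozen=True)
class RidgeParams:
    """Crazy-climber ridge extraction settings.

    n_climbers, n_sweeps
        Number of stochastic walkers and annealing sweeps.
    temperature_decay
        Geometric per-sweep decay of the Metropolis temperature.
    occupancy_percentile
        Percentile of the occupation density under a uniform random
        walk null above which a cell is called a ridge cell.
    min_duration_frac
        Minimum ridge length as a fraction of the series length;
        shorter ridges are discarded.  The default is calibrated on
        pure white noise so that spurious ridges (threshold
        exceedances are time-correlated at low frequency) survive at
        well under one component per two series.
    merge_tol_bins
        Ridges whose frequency tracks stay within this many frequency
        bins are merged (a real spectral component has width).
    min_cycles_in_record
        Ridges whose representative frequency completes fewer than this
        many cycles over the record are discarded: a periodicity claim
        needs at least one observed cycle.  The analysis band itself
        extends half an octave lower so such ridges keep their full
        spectral width.
    """

    n_climbers: int = 1000
    n_sweeps: int = 100
    temperature_decay: float = 0.99
    initial_temperature_frac: float = 0.1
    occupancy_percentile: float = 95.0
    min_duration_frac: float = 0.35
    merge_tol_bins: int = 2
    max_gap_columns: int = 3
    min_cycles_in_record: float = 1.0


@dataclass(frozen=True)
class SimilarityParams:
    """Constrained-coherency (CoCo) settings.

    freq_round
        Resolution (Hz) to which component frequencies are rounded when
        pooling pairs by frequency difference for the monotone
        envelope.
    envelope
        Strategy for the monotone representative curve: ``"cummin"``
        (running minimum over increasing frequency difference) or
        ``"isotonic"`` (antitonic regression).
    signal_mode
        ``"synthesize"`` re-synthesizes each component as a unit cosine
        at its representative frequency; ``"raw"`` excises the raw
        sub-series over the component's support.
    """

    freq_round: float = 0.01
    envelope: str = "cummin"
    signal_mode: str = "synthesize"


@dataclass(frozen=True)
class ValidationParams:
    """Cluster-validation settings (uniform-null Monte Carlo)."""

    n_replicates: int = 1000
    percentile: float = 95.0
    alpha: float = 0.05
    n_bootstrap: int = 1000


@dataclass(frozen=True)
class PipelineParams:
    wavelet: WaveletParams = field(default_factory=WaveletParams)
    threshold: ThresholdParams = field(default_factory=ThresholdParams)
    ridge: RidgeParams = field(default_factory=RidgeParams)
    similarity: SimilarityParams = field(default_factory=SimilarityParams)
    validation: ValidationParams = field(default_factory=ValidationParams)

    @classmethod
    def fast(cls) -> "PipelineParams":
        """Reduced Monte-Carlo sizes (M=200) for quick runs.

        Only the null-replicate counts shrink; ridge extraction keeps
        its full climber population, whose thinning measurably erodes
        ridge time supports.
        """
        p = cls()
        return replace(
            p,
            threshold=replace(p.threshold, n_replicates=200),
            validation=replace(p.validation, n_replicates=200, n_bootstrap=200),
        )

    @classmethod
    def from_yaml(cls, path) -> "PipelineParams":
        """Load parameters from a YAML file with section.keys mirroring
        the dataclass layout; missing keys keep their defaults."""
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sections = {
            "wavelet": WaveletParams,
            "threshold": ThresholdParams,
            "ridge": RidgeParams,
            "similarity": SimilarityParams,
            "validation": ValidationParams,
        }
        kwargs = {}
        for name, klass in sections.items():
            if name in raw:
                kwargs[name] = klass(**raw[name])
        return cls(**kwargs)
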