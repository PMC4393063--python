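"""Constrained-coherency (CoCo) similarity between spectral components.

Two components are compared through the magnitude-squared coherency of
their signals, ``C_xy(f) = |P_xy(f)|^2 / (P_xx(f) P_yy(f))``, with the
spectral densities estimated by Welch segment averaging.  Since the
components' frequencies are the quantity of interest, each component is
by default re-synthesized as a unit-amplitude cosine at its
representative frequency over a uniform length (the median component
length), so the similarity depends only on the frequency pair; the
coherency magnitude of pure tones is invariant to their phases.

Raw coherency is not guaranteed to fall off monotonically as the
frequency difference grows, so pairs are pooled by frequency
difference and the pooled curve is forced monotone non-increasing (its
valleys are non-increasing): the running minimum over increasing
frequency difference, or an antitonic regression.  The constrained
value at a pair's frequency difference is its CoCo similarity, which
lives in [0, 1] with unit self-similarity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import lru_cache
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import signal as sps

from .decompose import Component
from .params import SimilarityParams

# relative floor below which a Welch power estimate counts as zero
_POWER_FLOOR = 1e-10

__all__ = [
    "CoherencyCurve",
    "SimilarityMatrix",
    "component_signal",
    "coherency",
    "average_coherency",
    "coco_envelope",
    "similarity_matrix",
    "similarity_from_frequencies",
]


@dataclass(frozen=True)
class CoherencyCurve:
    """Pooled coherency vs frequency difference, before and after the
    monotone constraint."""

    delta_frequencies: np.ndarray  # Hz, ascending
    raw_coherency: np.ndarray
    constrained_coherency: np.ndarray

    def __post_init__(self):
        if np.any(np.diff(self.delta_frequencies) < 0):
            raise ValueError("delta_frequencies must be sorted ascending")
        if np.any(np.diff(self.constrained_coherency) > 1e-12):
            raise ValueError("constrained coherency must be non-increasing")

    def at(self, delta_f: float) -> float:
        """Constrained coherency at the envelope key closest to
        ``delta_f``."""
        i = int(np.argmin(np.abs(self.delta_frequencies - delta_f)))
        return float(self.constrained_coherency[i])


@dataclass(frozen=True)
class SimilarityMatrix:
    """Symmetric CoCo similarity with unit diagonal, entries in [0, 1]."""

    ids: Tuple[str, ...]
    values: np.ndarray
    envelope: Optional[CoherencyCurve] = None

    def __post_init__(self):
        v = self.values
        if v.shape != (len(self.ids), len(self.ids)):
            raise ValueError("matrix shape must match the id list")
        if not np.allclose(v, v.T):
            raise ValueError("similarity matrix must be symmetric")
        if not np.allclose(np.diag(v), 1.0):
            raise ValueError("similarity diagonal must be 1")
        if v.min() < -1e-12 or v.max() > 1 + 1e-12:
            raise ValueError("similarities must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.ids)

    def dissimilarity(self) -> np.ndarray:
        """1 - CoCo, zero diagonal."""
        d = 1.0 - self.values
        np.fill_diagonal(d, 0.0)
        return np.clip(d, 0.0, 1.0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)

    def write(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t")

    @classmethod
    def read(cls, path) -> "SimilarityMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(ids=tuple(df.index.astype(str)), values=df.to_numpy())


def component_signal(
    component_or_frequency,
    uniform_length: int,
    sampling_rate: float,
    phase: Optional[float] = None,
) -> np.ndarray:
    """Unit-amplitude cosine representing one component.

    Accepts either a :class:`Component` (whose representative frequency
    and, if set, phase are used) or a bare frequency in Hz.
    """
    if uniform_length < 8:
        raise ValueError("uniform_length must be at least 8")
    if isinstance(component_or_frequency, Component):
        f = component_or_frequency.frequency
        if phase is None and component_or_frequency.phase is not None:
            phase = component_or_frequency.phase
    else:
        f = float(component_or_frequency)
    if f >= sampling_rate / 2.0:
        raise ValueError(
            f"frequency {f:g} Hz is not below the Nyquist frequency "
            f"{sampling_rate / 2:g} Hz"
        )
    phi = 0.0 if phase is None else phase
    t = np.arange(uniform_length) / sampling_rate
    return np.cos(2 * np.pi * f * t + phi)


def coherency(
    x: np.ndarray, y: np.ndarray, sampling_rate: float
) -> Tuple[np.ndarray, np.ndarray]:
    """Magnitude-squared coherency on [0, Nyquist].

    Welch estimation with Hann windows of half the signal length and
    50% overlap; values are clipped to [0, 1] and frequencies with zero
    power in either signal are set to 0 with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("signals must have equal length")
    nperseg = max(8, len(x) // 2)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        freqs, cxy = sps.coherence(
            x, y, fs=sampling_rate, window="hann",
            nperseg=nperseg, noverlap=nperseg // 2,
        )
        _, pxx = sps.welch(x, fs=sampling_rate, window="hann",
                           nperseg=nperseg, noverlap=nperseg // 2)
        _, pyy = sps.welch(y, fs=sampling_rate, window="hann",
                           nperseg=nperseg, noverlap=nperseg // 2)
    # a bin with (numerically) no power in either signal carries no
    # coherence information: the ratio there is rounding noise
    bad = ~np.isfinite(cxy)
    bad |= pxx < _POWER_FLOOR * max(pxx.max(), 1e-300)
    bad |= pyy < _POWER_FLOOR * max(pyy.max(), 1e-300)
    if (~np.isfinite(cxy)).any():
        warnings.warn("zero-power segment; coherency set to 0", stacklevel=2)
    cxy = np.where(bad, 0.0, cxy)
    return freqs, np.clip(cxy, 0.0, 1.0)


@lru_cache(maxsize=200_000)
def _avg_coherency_cached(
    f_lo: float, f_hi: float, uniform_length: int, fs: float
) -> float:
    x = component_signal(f_lo, uniform_length, fs, phase=0.0)
    y = component_signal(f_hi, uniform_length, fs, phase=0.0)
    freqs, cxy = coherency(x, y, fs)
    band = (freqs >= f_lo - 1e-12) & (freqs <= f_hi + 1e-12)
    if not band.any():
        # both frequencies inside one Welch bin: take the nearest bin
        band = np.zeros_like(band)
        band[int(np.argmin(np.abs(freqs - 0.5 * (f_lo + f_hi))))] = True
    return float(np.mean(cxy[band]))


@lru_cache(maxsize=32)
def _band_coherency_matrix(
    kmin: int, kmax: int, r: float, uniform_length: int, fs: float
) -> np.ndarray:
    """Band-averaged coherency for every pair on the rounded frequency
    grid ``{kmin..kmax} * r``, computed in one vectorized pass.

    Mirrors the Welch estimator of :func:`coherency` (Hann window of
    half the length, 50% overlap, per-segment mean removal); entry
    (i, j) is the mean coherency over the frequency bins spanned by the
    two grid frequencies (nearest bin if they share one).  Agreement
    with the scalar scipy route is asserted in the test suite.
    """
    grid = np.arange(kmin, kmax + 1) * r
    K = len(grid)
    L = uniform_length
    nperseg = max(8, L // 2)
    step = nperseg - nperseg // 2
    starts = np.arange(0, L - nperseg + 1, step)
    win = sps.get_window("hann", nperseg)
    t = np.arange(L) / fs
    X = np.empty((K, len(starts), nperseg // 2 + 1), dtype=complex)
    for s, st in enumerate(starts):
        seg = np.cos(2 * np.pi * grid[:, None] * t[None, st : st + nperseg])
        seg = seg - seg.mean(axis=1, keepdims=True)
        X[:, s, :] = np.fft.rfft(seg * win[None, :], axis=1)
    pxx = np.mean(np.abs(X) ** 2, axis=1)  # (K, nbin)
    pxy = np.einsum("isb,jsb->ijb", X, np.conj(X)) / len(starts)
    denom = pxx[:, None, :] * pxx[None, :, :]
    with np.errstate(invalid="ignore", divide="ignore"):
        cxy = np.abs(pxy) ** 2 / denom
    cxy = np.clip(np.nan_to_num(cxy, nan=0.0), 0.0, 1.0)
    # bins with (numerically) no power in either tone carry no
    # coherence information; mirror the scalar route's zero policy
    weak = pxx < _POWER_FLOOR * np.maximum(
        pxx.max(axis=1, keepdims=True), 1e-300)
    cxy[weak[:, None, :] | weak[None, :, :]] = 0.0
    # self-coherency is identically 1; enforce exactly so equal
    # frequencies get dissimilarity 0, not float eps
    cxy[np.arange(K), np.arange(K), :] = 1.0

    fbins = np.fft.rfftfreq(nperseg, d=1.0 / fs)
    lo_bin = np.searchsorted(fbins, grid - 1e-12)  # first bin >= f
    hi_bin = np.searchsorted(fbins, grid + 1e-12) - 1  # last bin <= f
    nearest = np.argmin(
        np.abs(fbins[None, :] - grid[:, None]), axis=1
    )
    csum = np.concatenate(
        [np.zeros_like(cxy[..., :1]), np.cumsum(cxy, axis=-1)], axis=-1
    )
    out = np.empty((K, K))
    lo = np.minimum(lo_bin[:, None], lo_bin[None, :])
    hi = np.maximum(hi_bin[:, None], hi_bin[None, :])
    n_bins = hi - lo + 1
    ii, jj = np.indices((K, K))
    sums = csum[ii, jj, hi + 1] - csum[ii, jj, lo]
    out = sums / np.maximum(n_bins, 1)
    empty = n_bins < 1
    if empty.any():
        nb = np.minimum(nearest[:, None], nearest[None, :]) * 0 + np.argmin(
            np.abs(
                fbins[None, None, :]
                - 0.5 * (grid[:, None] + grid[None, :])[..., None]
            ),
            axis=-1,
        )
        out[empty] = cxy[ii, jj, nb][empty]
    return out


def average_coherency(
    x_component: Component,
    y_component: Component,
    uniform_length: int,
    sampling_rate: float,
) -> float:
    """Mean coherency over the frequency band spanned by the two
    components' representative frequencies (the single nearest bin if
    they coincide).  Symmetric in its arguments."""
    f_lo, f_hi = sorted((x_component.frequency, y_component.frequency))
    return _avg_coherency_cached(
        round(f_lo, 9), round(f_hi, 9), uniform_length, round(sampling_rate, 9)
    )


def coco_envelope(
    pairs: Sequence[Tuple[float, float]],
    weights: Optional[Sequence[float]] = None,
    strategy: str = "cummin",
) -> CoherencyCurve:
    """Monotone representative coherency curve.

    ``pairs`` are (frequency difference, raw coherency) observations;
    duplicated frequency differences are pooled by (weighted) mean.
    ``cummin`` takes the running minimum over increasing frequency
    difference; ``isotonic`` fits a least-squares non-increasing curve.
    """
    if len(pairs) == 0:
        raise ValueError("at least one pair is required")
    df = np.array([p[0] for p in pairs], dtype=float)
    raw = np.array([p[1] for p in pairs], dtype=float)
    w = np.ones_like(df) if weights is None else np.asarray(weights, dtype=float)
    keys, inv = np.unique(df, return_inverse=True)
    pooled = np.bincount(inv, weights=w * raw) / np.bincount(inv, weights=w)
    if strategy == "cummin":
        constrained = np.minimum.accumulate(pooled)
    elif strategy == "isotonic":
        from sklearn.isotonic import IsotonicRegression

        wk = np.bincount(inv, weights=w)
        iso = IsotonicRegression(increasing=False, out_of_bounds="clip")
        constrained = iso.fit_transform(keys, pooled, sample_weight=wk)
        constrained = np.minimum.accumulate(constrained)  # guard fp drift
    else:
        raise ValueError(f"unknown envelope strategy {strategy!r}")
    return CoherencyCurve(
        delta_frequencies=keys,
        raw_coherency=pooled,
        constrained_coherency=constrained,
    )


def _coco_values(
    frequencies: np.ndarray,
    sampling_rate: float,
    uniform_length: int,
    params: SimilarityParams,
) -> Tuple[np.ndarray, CoherencyCurve]:
    """CoCo similarity values (dense matrix) plus the envelope used;
    the unvalidated core behind :func:`similarity_from_frequencies`."""
    f = np.asarray(frequencies, dtype=float)
    n = len(f)
    if n < 2:
        raise ValueError("at least two components are required")
    r = params.freq_round
    f_key = np.round(f / r).astype(int)
    uniq, inv = np.unique(f_key, return_inverse=True)
    counts = np.bincount(inv).astype(float)
    m = len(uniq)

    # raw average coherency per unique frequency pair, from the cached
    # all-pairs grid matrix
    fs9 = round(sampling_rate, 9)
    kmin, kmax = int(f_key.min()), int(f_key.max())
    R = _band_coherency_matrix(kmin, kmax, r, uniform_length, fs9)
    sub = uniq - kmin
    ii, jj = np.triu_indices(m)
    raws = R[sub[ii], sub[jj]]
    # pair weights: component-pair counts; a lone frequency still
    # anchors the envelope at zero frequency difference
    w = counts[ii] * counts[jj]
    w[ii == jj] = np.maximum(counts[ii[ii == jj]] * (counts[ii[ii == jj]] - 1) / 2.0, 0.5)
    dfs = (uniq[jj] - uniq[ii]) * r
    curve = coco_envelope(list(zip(dfs, raws)), w, strategy=params.envelope)

    # look up the constrained value for every component pair; envelope
    # keys are on the same integer grid as the rounded frequencies
    ikeys = np.round(curve.delta_frequencies / r).astype(int)
    lut = np.full(int(ikeys.max()) + 1, np.nan)
    lut[ikeys] = curve.constrained_coherency
    kmat = np.abs(f_key[:, None] - f_key[None, :])
    values = lut[kmat]
    np.fill_diagonal(values, 1.0)
    values = np.clip(values, 0.0, 1.0)
    return values, curve


def similarity_from_frequencies(
    frequencies: Sequence[float],
    sampling_rate: float,
    uniform_length: int,
    params: SimilarityParams = SimilarityParams(),
    ids: Optional[Sequence[str]] = None,
) -> SimilarityMatrix:
    """CoCo similarity matrix for a set of representative frequencies.

    Frequencies are rounded to ``params.freq_round`` so that pairs pool
    into frequency-difference classes; the pooled raw coherencies are
    then constrained monotone and looked up per pair.
    """
    values, curve = _coco_values(
        np.asarray(frequencies, dtype=float), sampling_rate, uniform_length,
        params,
    )
    if ids is None:
        ids = tuple(f"c{i}" for i in range(len(values)))
    return SimilarityMatrix(ids=tuple(ids), values=values, envelope=curve)


def _uniform_length(components: Sequence[Component], sampling_rate: float) -> int:
    lengths = [
        int(round(c.duration * sampling_rate)) + 1 for c in components
    ]
    return max(8, int(np.median(lengths)))


def similarity_matrix(
    components: Sequence[Component],
    sampling_rate: float,
    params: SimilarityParams = SimilarityParams(),
    uniform_length: Optional[int] = None,
    series_lookup: Optional[Dict[str, "np.ndarray"]] = None,
) -> SimilarityMatrix:
    """Pairwise CoCo similarity between extracted components.

    The uniform comparison length is the median component length in
    samples (a component's raw length varies with its time support,
    but coherency needs equal-length signals).

    With ``params.signal_mode == "raw"`` the comparison uses the raw
    sub-series over each component's support (resampled to the uniform
    length) instead of a re-synthesized cosine; ``series_lookup`` must
    then map gene ids to their full value arrays.
    """
    if len(components) < 2:
        raise ValueError("at least two components are required")
    if uniform_length is None:
        uniform_length = _uniform_length(components, sampling_rate)
    ids = tuple(
        f"{c.gene_id}|{c.frequency:.4f}|{c.start_time:g}-{c.end_time:g}"
        for c in components
    )
    if params.signal_mode == "raw":
        if series_lookup is None:
            raise ValueError("raw signal mode requires series_lookup")
        return _raw_similarity_matrix(
            components, sampling_rate, uniform_length, params,
            series_lookup, ids,
        )
    return similarity_from_frequencies(
        [c.frequency for c in components],
        sampling_rate,
        uniform_length,
        params,
        ids=ids,
    )


def _raw_similarity_matrix(
    components: Sequence[Component],
    sampling_rate: float,
    uniform_length: int,
    params: SimilarityParams,
    series_lookup: Dict[str, np.ndarray],
    ids: Tuple[str, ...],
) -> SimilarityMatrix:
    """CoCo similarity on excised raw sub-series (the non-default
    signal mode).  Pairs still pool by frequency difference for the
    monotone envelope."""
    n = len(components)
    sigs = np.empty((n, uniform_length))
    for i, c in enumerate(components):
        full = np.asarray(series_lookup[c.gene_id], dtype=float)
        t = np.arange(len(full)) / sampling_rate
        lo = int(np.searchsorted(t, c.start_time - 1e-12))
        hi = int(np.searchsorted(t, c.end_time + 1e-12))
        seg = full[lo:max(hi, lo + 2)]
        sigs[i] = np.interp(
            np.linspace(0, len(seg) - 1, uniform_length),
            np.arange(len(seg)), seg,
        )
    r = params.freq_round
    f = np.array([c.frequency for c in components])
    pairs: List[Tuple[float, float]] = []
    raw = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            f_lo, f_hi = sorted((f[i], f[j]))
            freqs, cxy = coherency(sigs[i], sigs[j], sampling_rate)
            band = (freqs >= f_lo - 1e-12) & (freqs <= f_hi + 1e-12)
            if not band.any():
                band = np.zeros_like(band)
                band[int(np.argmin(np.abs(freqs - 0.5 * (f_lo + f_hi))))] = 1
            raw[i, j] = raw[j, i] = float(np.mean(cxy[band]))
            pairs.append((round(abs(f[j] - f[i]) / r) * r, raw[i, j]))
    pairs.append((0.0, 1.0))
    curve = coco_envelope(pairs, strategy=params.envelope)
    values = np.empty((n, n))
    for i in range(n):
        values[i, i] = 1.0
        for j in range(i + 1, n):
            values[i, j] = values[j, i] = curve.at(abs(f[j] - f[i]))
    return SimilarityMatrix(ids=ids, values=np.clip(values, 0, 1),
                            envelope=curve)
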