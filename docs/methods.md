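# Methods

## Model and assumptions

A gene's expression time course is modelled as a finite sum of
oscillatory components plus Gaussian noise,

    s(t) = Σ_k A_k · cos(2π f_k t + φ_k) · 1[t ∈ [a_k, b_k]] + ε(t),

where each component has its own frequency f_k, time support
[a_k, b_k] and phase φ_k. The working assumptions are:

* sampling is even; frequencies of interest lie below the Nyquist
  frequency and complete at least one full cycle inside the record;
* different spectral frequencies correspond to different biological
  processes, so frequency is the clustering variable; phase and
  amplitude are retained per component but do not enter the
  similarity;
* noise is white and Gaussian per series; its variance is estimated by
  the series' sample variance (a conservative choice: for signal-rich
  series the "noise" variance includes the signal's).

A cluster is a set of components, so a gene belongs to a cluster only
over its component's time support — cluster membership is
time-varying by construction.

## Decomposition

The CWT uses a complex analytic Morlet wavelet with centre frequency
ω₀ = 6 rad (the usual compromise between admissibility and
time–frequency resolution), an L1-type 1/a normalization — a unit
cosine then has ridge modulus 1 at every frequency while white-noise
modulus grows like a^(−1/2), which is why low frequencies are easier
to detect at a fixed noise floor — and a log-spaced scale grid with 12
voices per octave.

The analysed band runs from half a cycle per record (0.5/T) to the
Nyquist frequency, but ridges whose representative frequency falls
below one cycle per record (1/T) are discarded: a periodicity claim
needs at least one observed cycle, while analysing half an octave
below that floor keeps the spectral width of a 1/T component inside
the band instead of clipping it at the edge.

Boundary handling is circular (periodic) extension by default. The
method targets periodic profiles, for which circular extension is the
faithful one; symmetric reflection — available via
`WaveletParams.padding` — maps a one-cycle sinusoid at quarter phase
onto 1.5 cycles (the even extension of sin(2πt/T) is dominated by
3/(2T) content) and demonstrably destroys recovery of the slowest
components. A cone-of-influence flag (`edge_affected`) marks
components whose ridge runs closer to a record edge than the wavelet
e-folding time √2·a.

The white-noise threshold surface is the per-cell 95th percentile of
the CWT modulus over M = 1000 noise replicates (M = 200 in the fast
preset). Because the CWT is linear, the unit-variance surface is
computed once per grid and scaled by each series' sample standard
deviation; this is exact, not an approximation.

Ridge extraction is a stochastic relaxation: 1000 walkers drift
freely in time (reflecting at the record ends) and move in frequency
by a Metropolis rule on the excess modulus with a geometrically
cooled temperature (initial temperature 0.1 × max excess, decay 0.99
per sweep, 100 sweeps); occupation counts accumulated over the cooled
second half of the sweeps are compared with the 95th percentile of
the same dynamics on a flat landscape, and occupied cells with
positive excess are ridge cells. Per time column, contiguous ridge
runs collapse to their modulus-weighted centre; centres chain across
columns within 2 frequency bins and gaps of up to 3 columns; chained
paths closer than 2 bins merge (a spectral component has width).

The minimum ridge duration is 35% of the record. This default was
calibrated on pure white noise: threshold exceedances of a smooth
time–frequency field are time-correlated over roughly the wavelet
scale, so at low frequency they form blobs several columns long, and
shorter duration floors admit one to two spurious components per
noise-only series. At 35% the spurious rate is ≈0.35 components per
noise series (M = 1000), while components half the record long — the
shortest in the benchmark designs — are unaffected. Analyses hunting
for genuinely brief bursts should lower `min_duration_frac`
deliberately and expect more noise components.

The representative frequency is the excess-weighted geometric mean
along the ridge; the phase is the CWT phase at the ridge midpoint
rotated back to t = 0.

## Similarity (CoCo)

Components are re-synthesized as unit cosines at their representative
frequencies over a uniform length (the median component length in
samples), and compared by magnitude-squared coherency with Welch
estimation: Hann windows of half the uniform length, 50% overlap,
per-segment mean removal. The raw similarity of a pair is the mean
coherency over the frequency bins between the two component
frequencies (nearest bin if they share one). Re-synthesis makes the
similarity a function of the frequency pair alone — coherency
magnitude is invariant to the phases of pure tones — which is the
intended semantics (frequency defines the process) and allows aggressive
caching. Bins where either tone has numerically zero Welch power (a
Hann-windowed bin-centred tone leaks nothing beyond ±1 bin) carry no
coherence information and are set to 0 rather than left as rounding
noise.

Raw coherency is not monotone in the frequency difference, so pairs
are pooled by |f_x − f_y| (frequencies rounded to 0.01 Hz) and the
pooled curve is constrained to be monotone non-increasing. The default
constraint is the running minimum over increasing Δf — the simplest
curve through the valleys; weighted antitonic regression is available
(`SimilarityParams.envelope = "isotonic"`). The constrained value at a
pair's Δf is its CoCo similarity; equal frequencies get exactly 1.

## Clustering and validation

Ward linkage operates on 1 − CoCo treated as a squared inter-object
distance (the linkage receives its square root), via the standard
Lance–Williams recurrence; heights are then monotone. The merge
profile d_k (k = 2…n) records the cost of merging k clusters into
k − 1.

The cluster-number null draws n frequencies uniformly on
[min f, max f] — the convex hull of 1-D frequencies is that interval —
builds the CoCo similarity and Ward tree exactly as for the data, and
takes the per-k 95th percentile across M replicates. k₀ is the largest
k with d_k > d_k* (the last merge significantly more expensive than
chance), falling back to k₀ = 1 when no merge is. Exceedance uses a
relative tolerance of 10⁻⁶ so that exact-duplicate merges at height
zero on both sides never register.

Cluster significance cuts M null datasets at k₀ and pools their M·k₀
cluster-average silhouettes; each observed cluster's average
silhouette gets the add-one P-value (1 + #{null ≥ obs}) / (M·k₀ + 1),
so P ∈ (0, 1]. α defaults to 0.05. Singleton clusters score silhouette
0 by convention. Under null-generated data the procedure flags ≈3–4%
of clusters at α = 0.05 (calibration is asserted in the test suite).
Null cluster sizes float with the cut rather than being conditioned on
the observed sizes, which matches the resampling steps as stated.

Membership curves count, per significant cluster and time point, the
genes with a member component covering that time; the 95% band comes
from B = 1000 bootstrap resamples of the cluster's genes (B = 200 in
the fast preset).

## Evaluation

The discovery index matches classes (true frequencies) to clusters
greedily by ascending |Δf| under a 0.1 Hz cutoff, one-to-one — the
smallest between-class gap in the benchmark designs is 0.3 Hz.
Q_gj is the union of a gene's member-component supports within the
matched cluster (a gene may contribute several ridge fragments);
interval intersections and unions are computed exactly on closed
intervals in seconds. O_j is the gene count of the object that defines
index j in the enumeration: classes first (matched or not), then
superfluous significant clusters. Noise clusters are excluded from
matching — validation has already declared them unstructured.
Decomposition power pairs estimated with true components by log-scale
frequency proximity (0.25 octaves ≈ three grid bins) and computes the
duration Jaccard; overlap is capped so the value stays in [0, 1] even
when fragments double-cover a true support.

## Synthetic data

The generators produce exactly the benchmark families used throughout:
two-cosine signals with uniform random phases and scalable Gaussian
noise on 64 points over [0, 10] s (6.3 Hz sampling); the three-group
140-gene design with frequencies {0.1, 0.4, 0.8} Hz where each pair of
groups shares one frequency; and its time-varying variant where one
component per group occupies half the record, with N(0, 0.5²) noise —
the 0.5 is read as a standard deviation, and `GroupDesign.noise_sd` is
explicit about it. Phases are independent per gene per component; each
gene has a deterministic child RNG stream so datasets are
bit-reproducible under a seed. What this emulates well: stationary
sinusoidal components, abrupt entry/exit, white noise. What it does
not: amplitude drift, non-Gaussian or autocorrelated noise, uneven
sampling, and frequency chirps — passing tests therefore certify the
machinery on the stated model, not robustness to those departures.

## Problem sizes in the shipped studies

The replicated studies in `scripts/acceptance.py` and the test suite
use 50 replicate datasets per noise level for the discovery-index
study, 20 runs of the time-varying design, 100 replicates per cell of
the power-trend grids, and the fast preset (M = 200 null replicates;
full climber population). These sizes give Monte-Carlo standard
errors an order of magnitude below the comparison tolerances; the
original studies used 1000 replicates, and the replicate count is a
parameter of every study function.

## Known limitations

* Frequencies just above 1/T are estimated with upward bias when the
  true frequency sits at the reporting floor.
* Start/end times of high-frequency, short components suffer edge
  attrition of up to ~0.5 s at the benchmark sampling; supports are
  conservative (they rarely overshoot).
* The silhouette null and the merge-distance null share the uniform
  hull model; heavily non-uniform spurious frequencies (e.g. a comb)
  could bias both in the same direction.
* Ward on a non-Euclidean dissimilarity is a pragmatic, widely used
  choice; no ultrametric embedding claim is made.
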