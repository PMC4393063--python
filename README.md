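# dyclust — dynamic clustering of periodic expression time series

Genes move in and out of biological processes: a transcript can
oscillate with a cell-cycle process for part of an experiment and then
stop, or join a second process midway. Conventional clustering of
time-course expression data freezes each gene into one static cluster
and discards exactly this information. `dyclust` clusters the
*spectral components* of each profile instead of the profile itself,
so a gene belongs to a cluster only over the time interval in which it
actually oscillates at that cluster's frequency — cluster membership
becomes a function of time.

It is written for analysts of periodic bulk or single-cell expression
time courses (cell cycle, developmental oscillations, parasite life
cycles) sampled at evenly spaced time points, and for methodologists
who want a reference implementation of the validation machinery.

## Method

For each gene's series *s(t)* = (s₁, …, s_N):

1. **Time–frequency decomposition.** The continuous wavelet transform
   W(b, a) = (1/a) ∫ s(t) φ((t−b)/a) dt with a complex Morlet mother
   wavelet (ω₀ = 6) maps the series onto the time–frequency plane.
   Significance is referred to white noise: the CWT moduli of M
   Gaussian noise series with the series' own variance σ² give a
   per-cell 95th-percentile threshold surface W₀(t, f), and only the
   excess W′(t, f) = max{0, W(t, f) − W₀(t, f)} is kept. A stochastic
   "crazy climber" relaxation extracts ridges from W′; each ridge
   becomes a component with a representative frequency f, a start and
   end time, and a phase.
2. **Similarity.** Components are compared by magnitude-squared
   coherency C_xy(f) = |P_xy(f)|² / (P_xx(f) P_yy(f)) (Welch
   estimates), averaged over [f_x, f_y]. Pooled over pairs and forced
   monotone non-increasing in |f_x − f_y|, this yields the constrained
   coherency (CoCo) similarity in [0, 1].
3. **Clustering.** Agglomerative Ward linkage on the 1 − CoCo
   dissimilarity.
4. **Validation.** The number of clusters k₀ is the largest k whose
   merge distance d_k exceeds the 95th percentile d_k* of merge
   distances from datasets drawn uniformly over the hull
   [min f, max f] of the observed frequencies. Each of the k₀ clusters
   is then tested by silhouette width s(i) = (b(i) − a(i))/max{a, b}
   against the pooled cluster-average silhouettes of M such null
   datasets cut at k₀; clusters with P ≥ α are noise.
5. **Dynamics.** Because components carry time supports, each
   cluster's gene count is a curve over time, with a nonparametric
   bootstrap 95% band.

With known simulation truth, performance is scored by the discovery
index D_gj = |P_gj ∩ Q_gj| / |P_gj ∪ Q_gj| per gene and matched
class/cluster pair (true vs estimated time interval), aggregated as
D = Σ_j Σ_g D_gj / Σ_j O_j ∈ [0, 1], and by the decomposition power
Σw / (Σu + Σv − Σw) on true/estimated component durations.

## Worked example

```sh
dyclust simulate --design three-group --noise-level 0.5 --seed 3 --out demo
dyclust run --input demo.tsv --truth demo.truth.json --fast --seed 4 --out results/
```

The first command simulates the benchmark three-group design: 140
genes (20/40/80 per group), each the sum of two unit cosines from
{0.1, 0.4, 0.8} Hz with gene-specific random phases, 64 points on
[0, 10] s, noise sd 0.5, plus a truth file. The second runs the whole
pipeline and prints:

```
k0=3, 3 significant cluster(s), discovery index 0.995; results in results/
```

meaning the merge-distance test selected three clusters, all three
beat the silhouette null (P = 0.0017 each; they sit at 0.10, 0.39 and
0.78 Hz with 100, 120 and 60 member genes — see
`results/result.clusters.json`, which matches the 20/40/80 design
since each frequency is shared by two groups), and the recovered time
supports cover 99.5% of the generating ones in the Jaccard sense. The directory
also contains the per-component table, the CoCo similarity matrix, the
dendrogram (linkage text and Newick), per-cluster membership curves
with bootstrap bands, and per-gene discovery indices.

The same works from Python:

```python
from dyclust import GroupDesign, PipelineParams, run_pipeline, simulate_group_dataset

ds = simulate_group_dataset(GroupDesign.three_group(0.5), seed=3)
res = run_pipeline(ds, PipelineParams.fast(), seed=4)
print(res.clusters.k0, res.discovery.overall)
```

## Real-data recipe (*P. falciparum* IDC)

The method was developed against the intraerythrocytic developmental
cycle microarray time course of *Plasmodium falciparum* (HB3 strain;
530 annotated gene profiles × 46 hourly time points over 48 h). That
dataset is not shipped here; to reproduce the analysis:

1. Download supplementary table S2 of Bozdech et al. (2003), *PLoS
   Biology* 1(1):e5 — <http://dx.doi.org/10.1371/journal.pbio.0000005.st002> —
   and export it as a gene-by-time TSV with hour labels as the header.
2. The arrays for hours 23 and 29 are missing; imputation is part of
   the pipeline (k-nearest-neighbour over genes, k = 12 by default).
3. Run `dyclust run --input pfalciparum.tsv --time-unit h --seed 1
   --out pf_results/`. Reported cluster characteristics are periods
   (1/f) in hours; component phases order the genes within clusters.

## Notes

See `docs/methods.md` for the model assumptions, parameter defaults
and their calibration, numerical choices, and known limitations.
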