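"""Cluster-number selection, silhouette significance, membership."""

import numpy as np
import pytest

from dyclust.cluster import cut, merge_profile, ward_cluster, \
    ward_linkage_from_dissimilarity
from dyclust.decompose import Component
from dyclust.params import ValidationParams
from dyclust.similarity import similarity_from_frequencies
from dyclust.validate import (ClusterResult, ClusterStats, MembershipCurve,
                              MergeDistanceProfile, NullThresholdCurve,
                              cluster_significance, membership_curve,
                              null_merge_thresholds, select_k, silhouettes)


def comp(f, a=0.0, b=10.0, gene="g"):
    return Component(gene_id=gene, frequency=f, start_time=a, end_time=b,
                     mean_excess_modulus=1.0)


class TestNullThresholds:
    def test_degenerate_hull_rejected(self):
        with pytest.raises(ValueError, match="degenerate|identical"):
            null_merge_thresholds([0.4] * 10, M=5, seed=0)

    def test_same_seed_identical(self):
        freqs = [0.1, 0.2, 0.4, 0.6, 0.8]
        a = null_merge_thresholds(freqs, M=20, seed=3)
        b = null_merge_thresholds(freqs, M=20, seed=3)
        np.testing.assert_array_equal(a.thresholds, b.thresholds)

    def test_uniform_data_rarely_exceeds_null(self):
        # calibration: data drawn from the null itself exceeds the 95th
        # percentile threshold at only a few k values
        rng = np.random.default_rng(11)
        rates = []
        for rep in range(20):
            freqs = rng.uniform(0.1, 0.9, 40)
            sim = similarity_from_frequencies(freqs, 6.4, 64)
            prof = merge_profile(ward_cluster(sim))
            null = null_merge_thresholds(freqs, M=100,
                                         seed=int(rng.integers(2**31)))
            rates.append(np.mean(prof.heights > null.thresholds))
        assert np.mean(rates) < 0.15


class TestSelectK:
    def test_no_exceedance_falls_back_to_one(self):
        obs = MergeDistanceProfile(ks=np.array([2, 3, 4]),
                                   heights=np.array([1.0, 0.5, 0.1]))
        null = NullThresholdCurve(ks=np.array([2, 3, 4]),
                                  thresholds=np.array([2.0, 1.0, 0.5]),
                                  n_replicates=10, seed=0)
        assert select_k(obs, null) == 1

    def test_largest_exceeding_k_wins(self):
        obs = MergeDistanceProfile(ks=np.array([2, 3, 4]),
                                   heights=np.array([5.0, 1.0, 1.0]))
        null = NullThresholdCurve(ks=np.array([2, 3, 4]),
                                  thresholds=np.array([2.0, 2.0, 0.5]),
                                  n_replicates=10, seed=0)
        assert select_k(obs, null) == 4

    def test_scale_invariance(self):
        # multiplying all dissimilarities by c > 0 rescales both the
        # observed and the null profiles, leaving k0 unchanged
        rng = np.random.default_rng(5)
        freqs = np.concatenate([0.1 + 0.003 * rng.standard_normal(8),
                                0.7 + 0.003 * rng.standard_normal(8)])
        sim = similarity_from_frequencies(freqs, 6.4, 64)
        d = sim.dissimilarity()
        ks = None
        selected = []
        for c in (1.0, 7.5):
            Z = ward_linkage_from_dissimilarity(c * d)
            n = len(freqs)
            heights = np.sort(Z[:, 2])
            ksv = np.arange(2, n + 1)
            prof = MergeDistanceProfile(ks=ksv, heights=heights[n - ksv])
            null = null_merge_thresholds(freqs, M=60, seed=9)
            scaled_null = NullThresholdCurve(
                ks=null.ks, thresholds=np.sqrt(c) * null.thresholds,
                n_replicates=null.n_replicates, seed=null.seed)
            selected.append(select_k(prof, scaled_null))
        assert selected[0] == selected[1]


class TestSilhouettes:
    def test_hand_computed_values(self):
        # 1-D points {0, 1} in A and {10} in B, absolute differences
        d = np.abs(np.subtract.outer([0.0, 1.0, 10.0], [0.0, 1.0, 10.0]))
        s, avgs = silhouettes([0, 0, 1], d)
        assert s[0] == pytest.approx((10 - 1) / 10)  # a=1, b=10
        assert s[2] == 0.0  # singleton convention
        assert -1 <= s.min() and s.max() <= 1

    def test_equal_within_and_between_gives_zero(self):
        d = np.array([[0.0, 2.0, 2.0, 2.0],
                      [2.0, 0.0, 2.0, 2.0],
                      [2.0, 2.0, 0.0, 2.0],
                      [2.0, 2.0, 2.0, 0.0]])
        s, _ = silhouettes([0, 0, 1, 1], d)
        np.testing.assert_allclose(s, 0.0, atol=1e-12)

    def test_single_cluster_rejected(self):
        d = np.zeros((3, 3))
        with pytest.raises(ValueError, match="two clusters"):
            silhouettes([0, 0, 0], d)


class TestClusterSignificance:
    def test_tight_isolated_cluster_is_significant(self):
        rng = np.random.default_rng(0)
        freqs = np.concatenate([np.full(12, 0.1),
                                rng.uniform(0.3, 0.9, 12)])
        sim = similarity_from_frequencies(freqs, 6.4, 64)
        labels = cut(ward_cluster(sim), 2)
        comps = [comp(f, gene=f"c{i}") for i, f in enumerate(freqs)]
        res = cluster_significance(
            comps, labels, sim, 2, 6.4, 64,
            val_params=ValidationParams(n_replicates=200), seed=1)
        tight = min(res.clusters,
                    key=lambda c: abs(c.representative_frequency - 0.1))
        assert tight.p_value < 0.05 and tight.significant

    def test_p_values_in_unit_interval_and_never_zero(self):
        rng = np.random.default_rng(3)
        freqs = rng.uniform(0.1, 0.9, 20)
        sim = similarity_from_frequencies(freqs, 6.4, 64)
        labels = cut(ward_cluster(sim), 3)
        comps = [comp(f, gene=f"c{i}") for i, f in enumerate(freqs)]
        res = cluster_significance(
            comps, labels, sim, 3, 6.4, 64,
            val_params=ValidationParams(n_replicates=50), seed=2)
        for c in res.clusters:
            assert 0.0 < c.p_value <= 1.0

    def test_k0_one_short_circuits(self):
        comps = [comp(0.4, gene=f"c{i}") for i in range(5)]
        sim = similarity_from_frequencies([0.4] * 5, 6.4, 64)
        res = cluster_significance(comps, [0] * 5, sim, 1, 6.4, 64)
        assert res.k0 == 1
        assert len(res.clusters) == 1
        assert not res.clusters[0].significant

    def test_null_calibration_rejects_at_alpha_rate(self):
        # data drawn from the uniform reference itself should be called
        # significant at roughly the nominal rate
        rng = np.random.default_rng(2024)
        alpha, sig, tot = 0.05, 0, 0
        vp = ValidationParams(n_replicates=100, alpha=alpha)
        for run in range(60):
            freqs = rng.uniform(0.1, 0.9, 40)
            sim = similarity_from_frequencies(freqs, 6.4, 64)
            labels = cut(ward_cluster(sim), 3)
            comps = [comp(f, gene=f"c{i}") for i, f in enumerate(freqs)]
            res = cluster_significance(
                comps, labels, sim, 3, 6.4, 64, val_params=vp,
                seed=int(rng.integers(2**31)))
            for c in res.clusters:
                tot += 1
                sig += c.significant
        assert alpha / 2 <= sig / tot <= 2 * alpha


class TestMembershipCurve:
    def _result(self, comps, labels, k0=2):
        stats = []
        for cid in sorted(set(labels)):
            stats.append(ClusterStats(
                cluster_id=cid, n_components=labels.count(cid),
                n_genes=len({c.gene_id for c, l in zip(comps, labels)
                             if l == cid}),
                representative_frequency=0.4, average_silhouette=0.9,
                p_value=0.01, significant=True))
        return ClusterResult(k0=k0, labels=np.array(labels),
                             components=tuple(comps), clusters=tuple(stats),
                             alpha=0.05)

    def test_full_span_components_give_constant_counts(self):
        comps = [comp(0.4, 0, 10, gene=f"g{i}") for i in range(6)]
        res = self._result(comps, [0] * 6, k0=1)
        curve = membership_curve(res, np.linspace(0, 10, 11), B=50, seed=0)
        assert (curve.counts == 6).all()
        # identical genes: every resample recounts the same curve
        assert (curve.lower == 6).all() and (curve.upper == 6).all()

    def test_counts_follow_component_supports(self):
        comps = [comp(0.8, 0, 5, gene="a"), comp(0.8, 0, 5, gene="b"),
                 comp(0.8, 5, 10, gene="c")]
        res = self._result(comps, [0, 0, 0], k0=1)
        curve = membership_curve(res, np.array([2.0, 7.0]), B=20, seed=1)
        assert curve.counts[0, 0] == 2
        assert curve.counts[0, 1] == 1

    def test_band_covers_observed_count(self):
        rng = np.random.default_rng(4)
        comps = [comp(0.4, float(a), float(a + 4), gene=f"g{i}")
                 for i, a in enumerate(rng.uniform(0, 6, 25))]
        res = self._result(comps, [0] * 25, k0=1)
        curve = membership_curve(res, np.linspace(0, 10, 21), B=200, seed=2)
        assert (curve.lower <= curve.counts).all()
        assert (curve.counts <= curve.upper).all()

    def test_dynamic_design_high_frequency_cluster_drops_at_midpoint(
            self, dynamic_run):
        ds, res = dynamic_run
        sig = res.clusters.significant_clusters
        hi = max(sig, key=lambda c: c.representative_frequency)
        i = res.membership.cluster_ids.index(hi.cluster_id)
        t = res.membership.timepoints
        counts = res.membership.counts[i]
        # group 2's high-frequency component lives only on [0, 5): the
        # count of group-2 genes drops across t = 5 while group-1 rises
        def group_count(prefix, tt):
            return sum(
                1 for c, l in zip(res.clusters.components, res.clusters.labels)
                if l == hi.cluster_id and c.gene_id.startswith(prefix)
                and c.covers(tt))
        g2_before = np.mean([group_count("g2", x) for x in t[t < 5]])
        g2_after = np.mean([group_count("g2", x) for x in t[t > 5]])
        g1_before = np.mean([group_count("g1", x) for x in t[t < 5]])
        g1_after = np.mean([group_count("g1", x) for x in t[t > 5]])
        assert g2_after < g2_before
        assert g1_after > g1_before
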