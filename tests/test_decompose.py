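"""Wavelet decomposition: CWT, white-noise thresholding, ridge
extraction."""

import numpy as np
import pytest

from dyclust.decompose import (cwt_morlet, decompose, extract_ridges,
                               noise_threshold_surface, scale_grid_for,
                               threshold_map)
from dyclust.params import PipelineParams, WaveletParams
from dyclust.synthetic import ExpressionSeries

from conftest import cosine_series


class TestCwt:
    def test_zero_series_gives_zero_modulus(self, time_grid):
        s = ExpressionSeries("z", np.zeros(64), time_grid)
        assert not cwt_morlet(s).modulus.any()

    def test_linearity_under_scaling(self, time_grid):
        s1 = cosine_series(0.4, time_grid)
        s2 = ExpressionSeries("g", 2 * s1.values, time_grid)
        np.testing.assert_allclose(
            cwt_morlet(s2).modulus, 2 * cwt_morlet(s1).modulus, rtol=1e-12
        )

    def test_peak_frequency_of_pure_cosine(self, time_grid):
        m = cwt_morlet(cosine_series(0.4, time_grid))
        avg = m.modulus.mean(axis=1)
        peak = m.frequencies[np.argmax(avg)]
        # within one grid bin (12 voices/octave) of the true frequency
        assert abs(np.log2(peak / 0.4)) <= 1.0 / 12

    def test_agrees_with_pywavelets_on_shared_grid(self, time_grid):
        # independent implementation check: PyWavelets' complex Morlet
        # with matching center frequency, identical (periodic) series
        pywt = pytest.importorskip("pywt")
        s = cosine_series(0.5, time_grid)
        wl = WaveletParams()
        freqs = scale_grid_for(64, s.dt, wl)
        ours = cwt_morlet(s, freqs, wl).modulus
        fc = wl.omega0 / (2 * np.pi)
        scales = pywt.frequency2scale(f"cmor1.0-{fc}", freqs * s.dt)
        theirs, _ = pywt.cwt(s.values, scales, f"cmor1.0-{fc}",
                             sampling_period=s.dt)
        theirs = np.abs(theirs)
        # same normalization up to a per-scale constant: compare the
        # time profile correlation on interior columns at the peak row
        row = np.argmin(np.abs(freqs - 0.5))
        a, b = ours[row, 10:54], theirs[row, 10:54]
        r = np.corrcoef(a, b)[0, 1]
        assert r > 0.9
        # and the frequency of maximal response agrees within one bin
        assert abs(np.argmax(ours.mean(1)) - np.argmax(theirs.mean(1))) <= 1

    def test_short_and_nan_series_rejected(self, time_grid):
        with pytest.raises(ValueError, match="shorter"):
            cwt_morlet(ExpressionSeries("s", np.ones(4), np.arange(4.0)))
        vals = np.ones(64)
        vals[3] = np.nan
        with pytest.raises(ValueError, match="NaN"):
            cwt_morlet(ExpressionSeries("s", vals, time_grid))


class TestThresholdSurface:
    def test_constant_series_zero_surface_with_warning(self, time_grid):
        s = ExpressionSeries("c", np.ones(64), time_grid)
        freqs = scale_grid_for(64, s.dt, WaveletParams())
        with pytest.warns(UserWarning, match="constant"):
            surf = noise_threshold_surface(s, freqs, M=10, seed=0)
        assert not surf.thresholds.any()

    def test_surface_scales_linearly_with_sigma(self, time_grid):
        rng = np.random.default_rng(0)
        base = rng.standard_normal(64)
        freqs = scale_grid_for(64, 10 / 63, WaveletParams())
        s1 = ExpressionSeries("a", base, time_grid)
        s2 = ExpressionSeries("b", 2 * base, time_grid)
        a = noise_threshold_surface(s1, freqs, M=50, seed=1).thresholds
        b = noise_threshold_surface(s2, freqs, M=50, seed=1).thresholds
        np.testing.assert_allclose(b, 2 * a, rtol=1e-9)

    def test_percentile_matches_independent_monte_carlo(self, time_grid):
        # brute-force oracle: empirical 95th percentile of the CWT
        # modulus over many fresh white-noise draws at interior cells
        s = ExpressionSeries("n", np.random.default_rng(5).standard_normal(64),
                             time_grid)
        freqs = np.array([0.2, 0.5, 1.0])
        surf = noise_threshold_surface(s, freqs, M=1000, seed=2)
        sigma = np.std(s.values, ddof=1)
        rng = np.random.default_rng(99)
        wl = WaveletParams()
        mods = np.empty((4000, 3, 64))
        for k in range(4000):
            w = ExpressionSeries("w", rng.standard_normal(64), time_grid)
            mods[k] = cwt_morlet(w, freqs, wl).modulus
        oracle = sigma * np.percentile(mods, 95.0, axis=0)
        cells = (slice(None), slice(20, 44))
        np.testing.assert_allclose(
            surf.thresholds[cells], oracle[cells], rtol=0.08
        )


class TestThresholdMap:
    def test_zero_surface_is_identity(self, time_grid):
        m = cwt_morlet(cosine_series(0.4, time_grid))
        with pytest.warns(UserWarning, match="constant"):
            surf = noise_threshold_surface(
                ExpressionSeries("c", np.zeros(64), time_grid), m.frequencies,
                M=5, seed=0)
        out = threshold_map(m, surf)
        np.testing.assert_array_equal(out.modulus, m.modulus)

    def test_elementwise_rectified_difference(self, time_grid):
        import dataclasses

        m = cwt_morlet(cosine_series(0.4, time_grid))
        big = dataclasses.replace(
            noise_threshold_surface(cosine_series(0.4, time_grid),
                                    m.frequencies, M=5, seed=0),
            thresholds=np.full_like(m.modulus, 10.0))
        assert not threshold_map(m, big).modulus.any()
        one = dataclasses.replace(big, thresholds=np.ones_like(m.modulus))
        np.testing.assert_allclose(
            threshold_map(m, one).modulus, np.maximum(0, m.modulus - 1)
        )

    def test_shape_mismatch_rejected(self, time_grid):
        import dataclasses

        m = cwt_morlet(cosine_series(0.4, time_grid))
        bad = dataclasses.replace(
            noise_threshold_surface(cosine_series(0.4, time_grid),
                                    m.frequencies, M=5, seed=0),
            thresholds=np.zeros((2, 2)))
        with pytest.raises(ValueError, match="shape"):
            threshold_map(m, bad)


class TestRidgeExtraction:
    def test_zero_excess_yields_no_components(self, time_grid):
        m = cwt_morlet(ExpressionSeries("z", np.zeros(64), time_grid))
        assert extract_ridges(m) == []

    def test_full_duration_cosine_single_ridge(self, fast_params, time_grid):
        comps = decompose(cosine_series(0.4, time_grid), fast_params, seed=1)
        assert len(comps) == 1
        c = comps[0]
        assert abs(np.log2(c.frequency / 0.4)) <= 1.0 / 12
        assert c.duration >= 8.0  # >= 80% of the record
        # column-argmax oracle: the ridge follows the max-modulus row
        m = cwt_morlet(cosine_series(0.4, time_grid))
        oracle_rows = m.modulus.argmax(axis=0)
        ridge_freqs = [f for _, f, _ in c.ridge_path]
        assert np.median(ridge_freqs) == pytest.approx(
            np.median(m.frequencies[oracle_rows]), rel=0.1)

    def test_half_support_component_start_time(self, fast_params, time_grid):
        rng = np.random.default_rng(0)
        vals = np.where(time_grid >= 5, np.cos(2 * np.pi * 0.8 * time_grid),
                        0.0) + 0.05 * rng.standard_normal(64)
        comps = decompose(ExpressionSeries("h", vals, time_grid),
                          fast_params, seed=2)
        assert len(comps) >= 1
        c = max(comps, key=lambda c: c.duration)
        assert 4.0 <= c.start_time <= 6.0
        assert c.end_time >= 9.0

    def test_deterministic_under_seed(self, fast_params, time_grid):
        s = cosine_series(0.4, time_grid)
        a = decompose(s, fast_params, seed=7)
        b = decompose(s, fast_params, seed=7)
        assert [(c.frequency, c.start_time, c.end_time) for c in a] == [
            (c.frequency, c.start_time, c.end_time) for c in b]


class TestDecomposePipeline:
    def test_noise_free_group1_gene_two_components(self, fast_params,
                                                   time_grid):
        rng = np.random.default_rng(8)
        phi1, phi2 = rng.uniform(0, 2 * np.pi, 2)
        vals = (np.cos(2 * np.pi * 0.1 * time_grid + phi1)
                + np.cos(2 * np.pi * 0.8 * time_grid + phi2))
        comps = decompose(ExpressionSeries("g1", vals, time_grid),
                          fast_params, seed=3)
        assert len(comps) == 2
        f = sorted(c.frequency for c in comps)
        assert abs(np.log2(f[0] / 0.1)) <= 2.0 / 12
        assert abs(np.log2(f[1] / 0.8)) <= 2.0 / 12

    def test_white_noise_rarely_yields_components(self, time_grid):
        # spurious ridge calibration: the minimum-duration filter keeps
        # the pure-noise component rate below one per two series
        params = PipelineParams()  # full M=1000 thresholds
        rng = np.random.default_rng(42)
        n = 0
        for i in range(100):
            s = ExpressionSeries("n", rng.standard_normal(64), time_grid)
            n += len(decompose(s, params, seed=i, noise_seed=13))
        assert n / 100 < 0.5

    def test_dominant_component_recovered_when_weak_one_is(self, fast_params,
                                                           time_grid):
        # amplitude ratio 5: the strong component must never be the
        # one that goes missing
        from dyclust.synthetic import (TwoComponentConfig,
                                       simulate_two_component)
        bad = 0
        for i in range(40):
            cfg = TwoComponentConfig(base_frequency=0.3, delta_frequency=0.4,
                                     amplitude_ratio=5.0, noise_level=0.5,
                                     seed=i)
            s = simulate_two_component(cfg)
            comps = decompose(s, fast_params, seed=i, noise_seed=21)
            has_weak = any(abs(np.log2(c.frequency / 0.3)) <= 0.25
                           for c in comps)
            has_strong = any(abs(np.log2(c.frequency / 0.7)) <= 0.25
                             for c in comps)
            if has_weak and not has_strong:
                bad += 1
        assert bad == 0
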