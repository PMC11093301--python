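import numpy as np
import pytest

from fchybrid import (
    PipelineConfig,
    RoiTimeSeries,
    ValidationError,
    build_frequency_grid,
    cross_wavelet,
    cwt,
    dynamic_fc,
    pca_reduce_time,
    smooth,
    static_fc,
    wavelet_coherence,
)
from fchybrid.io_core import DimensionError


def _ts(data, tr=2.0, sid="s"):
    return RoiTimeSeries(sid, data, tr)


class TestStaticFC:
    def test_hand_computed_pair(self):
        # r = 11.5 / sqrt(5 * 28.75) for x=[1,2,3,4], y=[1,2,4,8]
        data = np.column_stack(
            [[1, 2, 3, 4], [1, 2, 4, 8], np.arange(4) % 2]
        ).astype(float)
        data = np.tile(data, (10, 1))  # meet the T >= 30 invariant
        mat = static_fc(_ts(data)).matrix
        assert mat[0, 1] == pytest.approx(11.5 / np.sqrt(5 * 28.75) , abs=1e-12)
        assert mat[0, 1] == pytest.approx(0.9591663, abs=1e-5)

    def test_perfect_anticorrelation_and_diagonal(self, rng):
        x = rng.standard_normal(40)
        data = np.column_stack([x, -x + 3.0, rng.standard_normal(40)])
        mat = static_fc(_ts(data)).matrix
        assert mat[0, 1] == pytest.approx(-1.0, abs=1e-12)
        assert np.array_equal(np.diag(mat), np.ones(3))

    def test_matches_textbook_oracle_on_random_draws(self, rng):
        def oracle(x, y):
            dx, dy = x - x.mean(), y - y.mean()
            return (dx * dy).sum() / np.sqrt((dx * dx).sum() * (dy * dy).sum())

        for _ in range(100):
            data = rng.standard_normal((35, 4))
            mat = static_fc(_ts(data)).matrix
            assert np.allclose(mat, mat.T, atol=1e-12)
            assert np.all((-1 <= mat) & (mat <= 1))
            for i in range(4):
                for j in range(i + 1, 4):
                    assert mat[i, j] == pytest.approx(
                        oracle(data[:, i], data[:, j]), abs=1e-12
                    )

    def test_zero_variance_column_names_roi(self, rng):
        data = rng.standard_normal((40, 3))
        ts = _ts(data)
        ts.data[:, 2] = 0.5  # mutate after construction to hit the op's own check
        with pytest.raises(ValidationError, match=r"\[2\]"):
            static_fc(ts)


class TestFrequencyGrid:
    def test_linear_partition_arithmetic(self):
        grid = build_frequency_grid(PipelineConfig(n_roi=3))
        assert grid.n_bands == 40
        assert grid.edges[1] - grid.edges[0] == pytest.approx(0.00175, abs=1e-12)
        assert grid.centers[0] == pytest.approx(0.010875, abs=1e-12)
        assert np.all((grid.centers > 0.01) & (grid.centers < 0.08))
        # Morlet relation f = omega0 / (2 pi s TR)
        back = grid.omega0 / (2 * np.pi * grid.scales * grid.tr)
        assert np.allclose(back, grid.centers, atol=1e-12)
        assert np.all(np.diff(grid.scales) < 0)  # centers increase => scales decrease

    def test_single_band_rejected(self):
        with pytest.raises(ValidationError):
            PipelineConfig(n_roi=3, n_bands=1)

    def test_log_spacing_option(self):
        grid = build_frequency_grid(PipelineConfig(n_roi=3, band_spacing="log"))
        ratios = grid.edges[1:] / grid.edges[:-1]
        assert np.allclose(ratios, ratios[0], atol=1e-12)


class TestCwt:
    def test_zero_signal_and_linearity(self, small_grid, small_config, rng):
        assert np.all(cwt(np.zeros(150), small_grid, small_config) == 0)
        x = rng.standard_normal(150)
        y = rng.standard_normal(150)
        wx = cwt(x, small_grid, small_config)
        wy = cwt(y, small_grid, small_config)
        wxy = cwt(2.5 * x - 0.5 * y, small_grid, small_config)
        assert np.allclose(wxy, 2.5 * wx - 0.5 * wy, atol=1e-10)

    def test_sinusoid_peaks_at_its_frequency(self, small_grid, small_config):
        t = np.arange(300) * small_config.tr
        sig = np.sin(2 * np.pi * 0.04 * t)
        w = cwt(sig, small_grid, small_config)
        peak = int(np.argmax(np.abs(w).mean(axis=1)))
        seg_width = small_grid.edges[1] - small_grid.edges[0]
        assert abs(small_grid.centers[peak] - 0.04) <= seg_width

    def test_agrees_with_reference_cwt(self, small_grid, small_config, rng):
        pywt = pytest.importorskip("pywt")
        x = rng.standard_normal(512)
        mine = cwt(x, small_grid, small_config)
        center = small_config.morlet_omega0 / (2 * np.pi)
        wavelet = pywt.ContinuousWavelet(f"cmor2.0-{center:.8f}")
        ref, _ = pywt.cwt(x, small_grid.scales, wavelet, method="fft")
        # same scale convention; amplitudes differ by a per-scale normalization
        # and by edge handling, so compare away from the boundaries
        interior = slice(100, -100)
        for row in range(0, small_grid.n_bands, 5):
            a = np.abs(mine[row, interior])
            b = np.abs(ref[row, interior])
            assert np.corrcoef(a, b)[0, 1] > 0.99

    def test_non_finite_rejected(self, small_grid, small_config):
        bad = np.ones(150)
        bad[3] = np.nan
        with pytest.raises(ValidationError):
            cwt(bad, small_grid, small_config)


class TestCrossWavelet:
    def test_self_pair_is_power(self, small_grid, small_config, rng):
        w = cwt(rng.standard_normal(150), small_grid, small_config)
        cw = cross_wavelet(w, w)
        assert np.allclose(cw.imag, 0, atol=1e-12)
        assert np.all(cw.real >= 0)

    def test_conjugate_symmetry_and_zero(self, small_grid, small_config, rng):
        wx = cwt(rng.standard_normal(150), small_grid, small_config)
        wy = cwt(rng.standard_normal(150), small_grid, small_config)
        assert np.allclose(cross_wavelet(wx, wy), np.conj(cross_wavelet(wy, wx)))
        assert np.all(cross_wavelet(wx, np.zeros_like(wy)) == 0)

    def test_shape_mismatch(self, small_grid, small_config, rng):
        wx = cwt(rng.standard_normal(150), small_grid, small_config)
        with pytest.raises(DimensionError):
            cross_wavelet(wx, wx[:, :-1])


class TestSmooth:
    def test_constant_preserved_exactly(self, small_grid, small_config):
        const = np.full((40, 150), 3.7)
        assert np.allclose(smooth(const, small_grid, small_config), 3.7, atol=1e-12)

    def test_linearity(self, small_grid, small_config, rng):
        a = rng.standard_normal((40, 150))
        b = rng.standard_normal((40, 150))
        lhs = smooth(2.0 * a + 3.0 * b, small_grid, small_config)
        rhs = 2.0 * smooth(a, small_grid, small_config) + 3.0 * smooth(b, small_grid, small_config)
        assert np.allclose(lhs, rhs, atol=1e-12)

    def test_interior_impulse_mass_preserved(self, small_grid, small_config):
        imp = np.zeros((40, 150))
        imp[20, 75] = 1.0
        out = smooth(imp, small_grid, small_config)
        assert out.sum() == pytest.approx(1.0, abs=1e-10)


class TestWaveletCoherence:
    def test_self_coherence_is_one(self, small_grid, small_config, rng):
        x = rng.standard_normal(150)
        wc = wavelet_coherence(x, x, small_grid, small_config)
        assert np.abs(wc - 1.0).max() < 1e-6

    def test_unsmoothed_degeneracy_any_pair(self, small_grid, small_config, rng):
        # |W_x W_y*|^2 == |W_x|^2 |W_y|^2 pointwise: without smoothing the
        # ratio is 1 for ANY pair — proof the smoother sits inside the modulus.
        x = rng.standard_normal(150)
        y = rng.standard_normal(150)
        wc = wavelet_coherence(x, y, small_grid, small_config, smoothing=False)
        assert np.abs(wc - 1.0).max() < 1e-9

    def test_bounded_after_smoothing(self, small_grid, small_config, rng):
        for _ in range(5):
            wc = wavelet_coherence(
                rng.standard_normal(150), rng.standard_normal(150),
                small_grid, small_config,
            )
            assert wc.min() >= 0.0 and wc.max() <= 1.0

    def test_shared_component_raises_band_coherence(self, small_grid, small_config):
        # pairs sharing a 0.04 Hz sinusoid separate from independent pairs at
        # the 0.04 Hz scale row, every seed
        band_row = int(np.argmin(np.abs(small_grid.centers - 0.04)))
        t = np.arange(150) * small_config.tr
        shared = np.sin(2 * np.pi * 0.04 * t)
        wins = 0
        for seed in range(20):
            r = np.random.default_rng(seed)
            x0, y0 = r.standard_normal(150), r.standard_normal(150)
            coh_indep = wavelet_coherence(x0, y0, small_grid, small_config)
            coh_shared = wavelet_coherence(
                x0 + 2 * shared, y0 + 2 * shared, small_grid, small_config
            )
            wins += (
                np.median(coh_shared[band_row]) > np.median(coh_indep[band_row])
            )
        assert wins == 20


class TestPcaReduceTime:
    def test_rank_one_map(self, small_config, rng):
        u = rng.standard_normal(40)
        v = rng.standard_normal(150)
        wc = np.outer(u, v)
        scores, k, retained = pca_reduce_time(wc, small_config)
        assert k == 1
        assert retained == pytest.approx(1.0, abs=1e-9)
        demeaned = wc - wc.mean(axis=1, keepdims=True)
        comp = scores[:, 0]
        recon = np.outer(comp, comp @ demeaned) / (comp @ comp)
        assert np.abs(recon - demeaned).max() < 1e-8

    def test_matches_svd_oracle(self, small_config, rng):
        for _ in range(20):
            wc = rng.random((12, 50))
            scores, k, retained = pca_reduce_time(wc, small_config)
            demeaned = wc - wc.mean(axis=1, keepdims=True)
            u, s, _ = np.linalg.svd(demeaned, full_matrices=False)
            var = s**2
            frac = np.cumsum(var) / var.sum()
            assert k == int(np.searchsorted(frac, 0.99 - 1e-12) + 1)
            assert retained == pytest.approx(frac[k - 1], abs=1e-10)
            for i in range(k):
                expected = u[:, i] * s[i]
                err = min(
                    np.abs(scores[:, i] - expected).max(),
                    np.abs(scores[:, i] + expected).max(),
                )
                assert err < 1e-8
            assert np.all(np.diff(frac) >= -1e-12)

    def test_full_rank_at_unit_threshold(self, small_config, rng):
        config = PipelineConfig(n_roi=3, pca_variance_threshold=1.0)
        wc = rng.random((8, 30))
        _, k, retained = pca_reduce_time(wc, config)
        assert k == 8  # demeaning over 30 samples keeps all 8 row-directions
        assert retained == pytest.approx(1.0, abs=1e-9)

    def test_sign_convention_nonnegative_sum(self, small_config, rng):
        scores, k, _ = pca_reduce_time(rng.random((10, 40)), small_config)
        sums = scores.sum(axis=0)
        assert np.all(sums >= -1e-9)

    def test_constant_map_reduces_to_zeros(self, small_config):
        scores, k, retained = pca_reduce_time(np.ones((6, 40)), small_config)
        assert k == 1 and retained == 1.0
        assert np.all(scores == 0)


class TestDynamicFC:
    @pytest.mark.filterwarnings("ignore:.*needed more than one component.*")
    def test_symmetry_shape_and_zero_diagonal(self, small_config, rng):
        config = PipelineConfig(n_roi=3, tr=2.0)
        grid = build_frequency_grid(config)
        ts = _ts(rng.standard_normal((60, 3)))
        out = dynamic_fc(ts, grid, config)
        assert out.tensor.shape == (3, 3, 40)
        assert np.array_equal(out.tensor[0, 1], out.tensor[1, 0])
        assert np.all(out.tensor[np.arange(3), np.arange(3)] == 0)
        assert np.all(out.variance_retained >= config.pca_variance_threshold)

    @pytest.mark.filterwarnings("ignore:.*needed more than one component.*")
    def test_shape_independent_of_scan_length(self, rng):
        # different sites record different numbers of time points; the tensor
        # shape must not depend on T
        config = PipelineConfig(n_roi=4, tr=2.0, n_bands=10)
        grid = build_frequency_grid(config)
        shapes = set()
        for t in (60, 100, 151):
            out = dynamic_fc(_ts(rng.standard_normal((t, 4))), grid, config)
            shapes.add(out.tensor.shape)
        assert shapes == {(4, 4, 10)}

    def test_multi_component_pairs_warn(self, small_config, rng):
        config = PipelineConfig(n_roi=3, tr=2.0, n_bands=12)
        grid = build_frequency_grid(config)
        ts = _ts(rng.standard_normal((80, 3)))
        with pytest.warns(UserWarning, match="more than one component"):
            dynamic_fc(ts, grid, config)

    @pytest.mark.filterwarnings("ignore:.*needed more than one component.*")
    def test_full_atlas_tensor_shape(self, rng):
        # the published geometry: 116 ROIs x 40 bands
        config = PipelineConfig(n_roi=116, tr=2.0)
        grid = build_frequency_grid(config)
        ts = _ts(rng.standard_normal((60, 116)))
        out = dynamic_fc(ts, grid, config)
        assert out.tensor.shape == (116, 116, 40)
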