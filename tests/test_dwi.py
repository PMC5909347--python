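"""ADC mapping: oracle equivalence, exact recovery, ROI statistics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from _oracles import ols_slope, trilinear
from vascquant import dwi
from vascquant import phantoms as ph


def biexp_stack(f, d, d_star, grid_shape=(3, 3, 2), s0=100.0):
    tmap = np.full(grid_shape, ph.VIABLE, np.uint8)
    spec = ph.DWIPhantomSpec(
        grid_shape=grid_shape, voxel_spacing=(1.8, 1.8, 1.8), tissue_map=tmap,
        class_params={ph.VIABLE: ph.IVIMParams(s0=s0, f=f, d=d, d_star=d_star)})
    stack, _ = ph.generate_dwi_phantom(spec)
    return stack


class TestFitAdcMap:
    def test_constant_signal_gives_zero_slope(self, mono_stack):
        stack = mono_stack(0.0)
        m = dwi.fit_adc_map(stack, (500, 750, 1000))
        assert np.all(np.abs(m.values) < 1e-15) and m.valid.all()

    @pytest.mark.parametrize("d", [1695e-6, 1320e-6, 346e-6, 166e-6])
    def test_noiseless_monoexponential_recovery(self, mono_stack, d):
        m = dwi.fit_adc_map(mono_stack(d), (500, 750, 1000))
        np.testing.assert_allclose(m.values, d, rtol=1e-10)

    def test_biexponential_matches_ols_oracle(self):
        stack = biexp_stack(f=0.1, d=1.0e-3, d_star=1.0e-2)
        m = dwi.fit_adc_map(stack, (500, 750, 1000))
        b = np.array([500.0, 750.0, 1000.0])
        logs = np.log(stack.signal[0, 0, 0, np.isin(stack.b_values, b)])
        expect = -ols_slope(b, logs)
        np.testing.assert_allclose(m.values, expect, rtol=1e-12)

    def test_oracle_equivalence_on_random_grid(self):
        """Every fitted slope equals the normal-equations OLS oracle."""
        rng = np.random.default_rng(0)
        shape = (6, 5, 4)
        sig = rng.uniform(1.0, 100.0, shape + (10,))
        stack = dwi.BValueStack(signal=sig,
                                b_values=np.asarray(ph.DEFAULT_B_VALUES),
                                voxel_spacing=np.ones(3))
        subset = np.array([50.0, 100.0, 150.0])
        m = dwi.fit_adc_map(stack, subset)
        cols = np.isin(stack.b_values, subset)
        for idx in np.ndindex(shape):
            expect = -ols_slope(subset, np.log(sig[idx][cols]))
            assert abs(m.values[idx] - expect) <= 1e-12 * max(1.0, abs(expect))

    def test_nonpositive_signal_marks_invalid(self, mono_stack):
        stack = mono_stack(1e-3)
        stack.signal[1, 1, 0, 7] = 0.0  # b=500 sample
        m = dwi.fit_adc_map(stack, (500, 750, 1000))
        assert not m.valid[1, 1, 0] and m.valid.sum() == m.valid.size - 1
        assert m.values[1, 1, 0] == 0.0

    def test_subset_errors(self, mono_stack):
        stack = mono_stack(1e-3)
        with pytest.raises(ValueError):
            dwi.fit_adc_map(stack, (500,))
        with pytest.raises(ValueError):
            dwi.fit_adc_map(stack, (500, 999))


class TestAdcPerf:
    def test_single_exponential_gives_zero(self, mono_stack):
        perf = dwi.compute_adc_perf(mono_stack(1.2e-3))
        assert np.all(np.abs(perf.values) < 1e-12)

    def test_piecewise_recovery(self):
        stack = ph.generate_piecewise_phantom(1000e-6, 723e-6)
        np.testing.assert_allclose(dwi.compute_adc_perf(stack).values,
                                   723e-6, rtol=1e-9)

    def test_increasing_in_perfusion_fraction_and_oracle_equal(self):
        prev = -1.0
        b_low = np.array([50.0, 100.0, 150.0])
        b_high = np.array([500.0, 750.0, 1000.0])
        for f in (0.05, 0.1, 0.15, 0.2, 0.25, 0.3):
            stack = biexp_stack(f=f, d=1.0e-3, d_star=1.0e-2)
            perf = dwi.compute_adc_perf(stack)
            v = perf.values[0, 0, 0]
            # oracle: two independent OLS fits, subtracted
            s = stack.signal[0, 0, 0]
            low = -ols_slope(b_low, np.log(s[np.isin(stack.b_values, b_low)]))
            high = -ols_slope(b_high, np.log(s[np.isin(stack.b_values, b_high)]))
            assert v == pytest.approx(low - high, rel=1e-12)
            assert v > prev
            prev = v

    def test_nonnegative_before_clipping_on_biexponential_grid(self):
        for f in np.linspace(0.02, 0.9, 8):
            for d_star_mult in (2.0, 5.0, 20.0):
                stack = biexp_stack(f=f, d=1e-3, d_star=d_star_mult * 1e-3,
                                    grid_shape=(1, 1, 1))
                perf = dwi.compute_adc_perf(stack, clip_negative=False)
                assert perf.values[0, 0, 0] >= 0.0

    def test_limit_f_to_zero(self):
        """As f -> 0, ADC_diff -> d and ADC_perf -> 0 monotonically."""
        d = 1.0e-3
        prev_perf = np.inf
        prev_diff_err = np.inf
        for f in (0.1, 0.01, 0.001):
            stack = biexp_stack(f=f, d=d, d_star=1e-2, grid_shape=(1, 1, 1))
            diff = dwi.compute_adc_diff(stack).values[0, 0, 0]
            perf = dwi.compute_adc_perf(stack).values[0, 0, 0]
            assert perf < prev_perf
            assert abs(diff - d) < prev_diff_err
            prev_perf, prev_diff_err = perf, abs(diff - d)
        assert perf < 1e-5 and abs(diff - d) < 1e-5

    def test_missing_required_b_values(self):
        sig = np.ones((2, 2, 2, 3))
        stack = dwi.BValueStack(signal=sig, b_values=np.array([0.0, 500.0, 750.0]),
                                voxel_spacing=np.ones(3))
        with pytest.raises(ValueError):
            dwi.compute_adc_perf(stack)


class TestNoiseRecovery:
    def test_rician_snr50_median_error_below_5pct(self):
        """Parameter recovery under magnitude noise at SNR 50 (b=0).

        The delivered image averages six acquisitions (three orthogonal
        diffusion directions, two signal averages), as the emulated
        protocol does; per-acquisition sigma is s0/50.
        """
        d = 1.0e-3
        tmap = np.full((12, 12, 12), ph.VIABLE, np.uint8)
        spec = ph.DWIPhantomSpec(
            grid_shape=(12, 12, 12), voxel_spacing=(1.8, 1.8, 1.8),
            tissue_map=tmap,
            class_params={ph.VIABLE: ph.IVIMParams(s0=100.0, f=0.0, d=d)},
            noise_model="rician", noise_sigma=2.0, n_averages=6, seed=123)
        stack, _ = ph.generate_dwi_phantom(spec)
        m = dwi.compute_adc_diff(stack)
        err = np.abs(m.values[m.valid] - d) / d
        assert np.median(err) < 0.05


class TestRoiStatistics:
    def test_uniform_map(self, mono_stack):
        m = dwi.compute_adc_diff(mono_stack(500e-6))
        roi = dwi.ROIMask(mask=np.ones(m.values.shape, bool))
        s = dwi.roi_statistics(m, roi)
        assert s.minimum == pytest.approx(500e-6, rel=1e-12)
        assert s.mean == pytest.approx(500e-6, rel=1e-12)
        assert s.maximum == pytest.approx(500e-6, rel=1e-12)
        assert s.n_voxels == m.values.size

    def test_rim_and_core_extremes(self):
        """Dense viable rim at 166e-6 and necrotic core at 1695e-6 set the
        ROI minimum and maximum."""
        tmap = np.zeros((4, 4, 2), np.uint8)
        tmap[:2] = ph.VIABLE
        tmap[2] = ph.NECROSIS
        tmap[3] = ph.STROMA
        spec = ph.DWIPhantomSpec(
            grid_shape=(4, 4, 2), voxel_spacing=(1.8, 1.8, 1.8),
            tissue_map=tmap,
            class_params={
                ph.VIABLE: ph.IVIMParams(s0=100.0, f=0.0, d=166e-6),
                ph.NECROSIS: ph.IVIMParams(s0=100.0, f=0.0, d=1695e-6),
                ph.STROMA: ph.IVIMParams(s0=100.0, f=0.0, d=900e-6)})
        stack, _ = ph.generate_dwi_phantom(spec)
        m = dwi.compute_adc_diff(stack)
        s = dwi.roi_statistics(m, dwi.ROIMask(mask=tmap != ph.BACKGROUND))
        assert s.minimum == pytest.approx(166e-6, rel=1e-9)
        assert s.maximum == pytest.approx(1695e-6, rel=1e-9)

    def test_mean_arithmetic(self):
        vals = np.array([100e-6, 200e-6, 600e-6]).reshape(3, 1, 1)
        m = dwi.ADCMap(values=vals, valid=np.ones((3, 1, 1), bool),
                       b_subset=(500., 750., 1000.), kind="diff")
        s = dwi.roi_statistics(m, dwi.ROIMask(mask=np.ones((3, 1, 1), bool)))
        assert s.mean == pytest.approx(300e-6)

    def test_empty_intersection_raises(self):
        m = dwi.ADCMap(values=np.ones((2, 2, 2)),
                       valid=np.zeros((2, 2, 2), bool),
                       b_subset=(500., 750., 1000.), kind="diff")
        with pytest.raises(dwi.NoValidVoxelsError):
            dwi.roi_statistics(m, dwi.ROIMask(mask=np.ones((2, 2, 2), bool)))

    @settings(derandomize=True, max_examples=25)
    @given(st.lists(st.floats(1e-6, 3e-3), min_size=2, max_size=27))
    def test_order_invariance_and_min_mean_max(self, values):
        n = len(values)
        arr = np.array(values).reshape(n, 1, 1)
        m = dwi.ADCMap(values=arr, valid=np.ones((n, 1, 1), bool),
                       b_subset=(500., 750., 1000.), kind="diff")
        roi = dwi.ROIMask(mask=np.ones((n, 1, 1), bool))
        s1 = dwi.roi_statistics(m, roi)
        perm = np.random.default_rng(0).permutation(n)
        m2 = dwi.ADCMap(values=arr[perm], valid=np.ones((n, 1, 1), bool),
                        b_subset=(500., 750., 1000.), kind="diff")
        s2 = dwi.roi_statistics(m2, roi)
        assert s1.minimum == s2.minimum and s1.maximum == s2.maximum
        assert s1.mean == pytest.approx(s2.mean, rel=1e-12)
        assert s1.n_voxels == s2.n_voxels
        assert s1.minimum <= s1.mean + 1e-18 and s1.mean <= s1.maximum + 1e-18


class TestResampling:
    def _ramp_map(self, shape=(8, 8, 4)):
        x = np.arange(shape[0], dtype=float)
        vals = np.broadcast_to(x[:, None, None], shape).copy()
        return dwi.ADCMap(values=vals, valid=np.ones(shape, bool),
                          b_subset=(500., 750., 1000.), kind="diff",
                          voxel_spacing=np.ones(3))

    def test_identity_passthrough(self):
        m = self._ramp_map()
        out = dwi.resample_to_reference(m, m.affine, m.values.shape)
        assert out.values.tobytes() == m.values.tobytes()

    def test_constant_map_on_coarser_grid(self):
        shape = (8, 8, 4)
        m = dwi.ADCMap(values=np.full(shape, 7e-4), valid=np.ones(shape, bool),
                       b_subset=(500., 750., 1000.), kind="diff",
                       voxel_spacing=np.ones(3))
        ref_affine = np.diag([2.0, 2.0, 2.0, 1.0])
        out = dwi.resample_to_reference(m, ref_affine, (4, 4, 2))
        np.testing.assert_allclose(out.values[out.valid], 7e-4)

    def test_ramp_matches_interpolation_oracle(self):
        m = self._ramp_map()
        ref_affine = np.diag([2.0, 2.0, 2.0, 1.0])
        out = dwi.resample_to_reference(m, ref_affine, (4, 4, 2))
        for idx in np.ndindex(4, 4, 2):
            world = ref_affine @ np.array([*idx, 1.0])
            src = np.linalg.inv(m.affine) @ world
            expect = trilinear(m.values, src[:3])
            assert out.values[idx] == pytest.approx(expect, rel=1e-12)

    def test_non_overlapping_grids_rejected(self):
        m = self._ramp_map()
        shifted = np.eye(4)
        shifted[:3, 3] = 1000.0
        with pytest.raises(ValueError):
            dwi.resample_to_reference(m, shifted, (4, 4, 2))


class TestContourPropagation:
    def test_identity(self):
        mask = np.zeros((6, 6, 4), bool)
        mask[2:4, 2:4, 1:3] = True
        roi = dwi.ROIMask(mask=mask, voxel_spacing=np.ones(3))
        out = dwi.propagate_contour(roi, roi.affine, mask.shape)
        assert np.array_equal(out.mask, mask) and out.label == roi.label

    def test_full_volume_stays_full(self):
        roi = dwi.ROIMask(mask=np.ones((8, 8, 4), bool),
                          voxel_spacing=np.ones(3))
        out = dwi.propagate_contour(roi, np.diag([2., 2., 2., 1.]), (4, 4, 2))
        assert out.mask.all()

    def test_sphere_volume_preserved_across_resolution(self):
        """A sphere at 2x resolution holds ~8x the voxels of its coarse copy."""
        n = 24
        coords = np.indices((n, n, n), dtype=float) - (n - 1) / 2
        fine = (np.sum(coords ** 2, axis=0) <= (n / 3) ** 2)
        roi = dwi.ROIMask(mask=fine, voxel_spacing=np.ones(3))
        coarse = dwi.propagate_contour(roi, np.diag([2., 2., 2., 1.]),
                                       (n // 2, n // 2, n // 2))
        assert abs(fine.sum() - 8 * coarse.mask.sum()) <= 0.1 * fine.sum()
        # membership stays binary
        assert coarse.mask.dtype == bool


class TestRendering:
    def test_window_endpoints_and_midpoint(self):
        vals = np.array([0.0, 1500e-6, 3000e-6, 4000e-6]).reshape(4, 1, 1)
        m = dwi.ADCMap(values=vals, valid=np.ones((4, 1, 1), bool),
                       b_subset=(500., 750., 1000.), kind="diff")
        r = dwi.render_8bit(m, window=(0.0, 3000e-6))
        assert r.index[0, 0, 0] == 0
        assert r.index[1, 0, 0] == 128  # 127.5 rounds half away from zero
        assert r.index[2, 0, 0] == 255
        assert r.index[3, 0, 0] == 255  # clamped above window
        assert r.rgb.shape == (4, 1, 1, 3) and r.rgb.dtype == np.uint8

    def test_quantisation_error_bound(self):
        rng = np.random.default_rng(1)
        vals = rng.uniform(0, 3000e-6, (5, 5, 2))
        m = dwi.ADCMap(values=vals, valid=np.ones((5, 5, 2), bool),
                       b_subset=(500., 750., 1000.), kind="diff")
        r = dwi.render_8bit(m, window=(0.0, 3000e-6))
        recon = r.index / 255.0 * 3000e-6
        assert np.max(np.abs(recon - vals)) <= 3000e-6 / 255.0

    def test_degenerate_window_rejected(self):
        m = dwi.ADCMap(values=np.zeros((1, 1, 1)),
                       valid=np.ones((1, 1, 1), bool),
                       b_subset=(500., 750., 1000.), kind="diff")
        with pytest.raises(ValueError):
            dwi.render_8bit(m, window=(1e-3, 1e-3))


class TestTumourVolume:
    def test_unit_voxels(self):
        mask = np.ones((10, 10, 10), bool)
        assert dwi.tumour_volume(dwi.ROIMask(mask=mask),
                                 (1.0, 1.0, 1.0)) == pytest.approx(1.0)

    def test_ct_voxel_size(self):
        mask = np.ones((10, 10, 10), bool)
        v = dwi.tumour_volume(dwi.ROIMask(mask=mask), (0.42, 0.42, 0.75))
        assert v == pytest.approx(0.1323)

    def test_single_isotropic_voxel(self):
        mask = np.zeros((2, 2, 2), bool)
        mask[0, 0, 0] = True
        v = dwi.tumour_volume(dwi.ROIMask(mask=mask), (0.6, 0.6, 0.6))
        assert v == pytest.approx(2.16e-4)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            dwi.tumour_volume(dwi.ROIMask(mask=np.zeros((2, 2, 2), bool)),
                              (1, 1, 1))
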