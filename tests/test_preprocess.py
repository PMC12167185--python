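"""Smoothing, the signal-dropout rule, registration, repetition averaging."""

import math

import numpy as np
import pytest
from scipy.ndimage import gaussian_filter, shift as nd_shift

from mpmri import preprocess, simulate
from mpmri.exceptions import ParameterError
from mpmri.io import DwiStack, VoxelGrid3D


class TestGaussianSmooth:
    def test_constant_image_unchanged(self):
        grid = VoxelGrid3D(np.full((8, 8, 8), 3.5), (0.5, 0.5, 0.5))
        out = preprocess.gaussian_smooth(grid, 1.5)
        np.testing.assert_allclose(out.data, 3.5, rtol=1e-12)

    def test_impulse_matches_analytic_kernel(self):
        # width 1.5 mm FWHM at 0.5 mm spacing -> sigma ~ 1.2739 voxels
        sigma = 1.5 / (2 * math.sqrt(2 * math.log(2))) / 0.5
        assert sigma == pytest.approx(1.2739, abs=1e-4)
        n = 33
        data = np.zeros((n, n, n))
        data[n // 2, n // 2, n // 2] = 1.0
        out = preprocess.gaussian_smooth(
            VoxelGrid3D(data, (0.5, 0.5, 0.5)), 1.5)
        # dense separable convolution with the truncated sampled Gaussian
        r = int(3 * sigma + 0.5)
        i = np.arange(-r, r + 1)
        k = np.exp(-(i ** 2) / (2 * sigma ** 2))
        k /= k.sum()
        expected = k[:, None, None] * k[None, :, None] * k[None, None, :]
        center = slice(n // 2 - r, n // 2 + r + 1)
        np.testing.assert_allclose(out.data[center, center, center],
                                   expected, atol=1e-12)
        assert out.data.sum() == pytest.approx(1.0, rel=1e-3)

    def test_sum_preserved_interior_support(self, rng):
        data = np.zeros((24, 24, 24))
        data[8:16, 8:16, 8:16] = rng.random((8, 8, 8))
        grid = VoxelGrid3D(data, (1.0, 1.0, 1.0))
        out = preprocess.gaussian_smooth(grid, 2.0)
        assert out.data.sum() == pytest.approx(data.sum(), rel=1e-3)

    def test_semigroup_two_passes(self, rng):
        data = gaussian_filter(rng.random((28, 28, 28)), 1.0)
        grid = VoxelGrid3D(data, (1.0, 1.0, 1.0))
        w = 2.0
        twice = preprocess.gaussian_smooth(
            preprocess.gaussian_smooth(grid, w), w)
        once = preprocess.gaussian_smooth(grid, w * math.sqrt(2))
        interior = (slice(8, -8),) * 3
        np.testing.assert_allclose(twice.data[interior], once.data[interior],
                                   rtol=1e-3)

    def test_nonpositive_width_rejected(self):
        grid = VoxelGrid3D(np.ones((4, 4, 4)), (1, 1, 1))
        with pytest.raises(ParameterError):
            preprocess.gaussian_smooth(grid, 0.0)

    def test_roi_mean_of_constant_region_preserved(self):
        data = np.zeros((16, 16, 16))
        data[4:12, 4:12, 4:12] = 7.0
        out = preprocess.gaussian_smooth(
            VoxelGrid3D(data, (1, 1, 1)), 1.0)
        inner = out.data[7:9, 7:9, 7:9]  # deep interior of the region
        np.testing.assert_allclose(inner, 7.0, rtol=1e-6)


def _stack_with_scales(scales, seed=0, nb=2, shape=(1, 16, 16)):
    """Stack whose repetitions are a fixed pattern times per-rep scales."""
    rng = np.random.default_rng(seed)
    base = np.zeros(shape[1:])
    base[4:12, 4:12] = 100.0
    base += rng.random(shape[1:])
    vols = np.empty((nb, len(scales), *shape))
    for b in range(nb):
        for r, s in enumerate(scales):
            vols[b, r, 0] = base * s * (1.0 - 0.1 * b)
    return DwiStack(vols, [0.0, 500.0][:nb], (1.0, 1.0, 1.0))


class TestDropoutRule:
    def test_single_dim_repetition_straddles_threshold(self):
        # nine repetitions at full brightness, one at 60% -> only that one
        # falls below 2/3 of the bright-half mean
        scales = [1.0] * 9 + [0.6]
        stack = _stack_with_scales(scales)
        report = preprocess.detect_signal_dropout(stack)
        excluded = report.excluded_set()
        assert excluded == {(b, 9, 0) for b in range(stack.n_b)}

    def test_all_identical_none_excluded(self):
        stack = _stack_with_scales([1.0] * 6)
        report = preprocess.detect_signal_dropout(stack)
        assert report.excluded_set() == set()
        assert not stack.excluded.any()

    def test_threshold_sits_at_two_thirds(self):
        # repetitions just above 2/3 of the bright-half mean survive,
        # those just below are excluded
        scales = [1.0, 1.0, 1.0, 1.0, 0.68, 0.65]
        stack = _stack_with_scales(scales)
        report = preprocess.detect_signal_dropout(stack)
        assert report.excluded_set() == {(b, 5, 0) for b in range(stack.n_b)}

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(11)
        scales = rng.uniform(0.3, 1.2, size=8)
        stack = _stack_with_scales(scales, seed=3)
        report = preprocess.detect_signal_dropout(stack)

        # independent re-implementation per (z, b)
        expected = set()
        R = stack.n_repetitions
        for b in range(stack.n_b):
            for z in range(stack.n_slices):
                fg = preprocess.foreground_mask(stack.volumes[b, :, z])
                m = [stack.volumes[b, r, z][fg].mean() for r in range(R)]
                top = sorted(m, reverse=True)[: math.ceil(R / 2)]
                thr = (2.0 / 3.0) * (sum(top) / len(top))
                for r in range(R):
                    if m[r] < thr:
                        expected.add((b, r, z))
        assert report.excluded_set() == expected

    def test_permutation_invariance_of_decision(self):
        scales = [1.0, 0.9, 0.5, 1.1, 0.55]
        stack = preprocess.detect_signal_dropout(_stack_with_scales(scales))
        perm = [3, 2, 0, 4, 1]
        permuted = preprocess.detect_signal_dropout(
            _stack_with_scales([scales[i] for i in perm]))
        orig = {(b, perm.index(r), z) for b, r, z in stack.excluded_set()}
        assert orig == permuted.excluded_set()

    def test_empty_foreground_flags_slice_with_warning(self):
        vols = np.zeros((1, 3, 2, 8, 8))
        vols[0, :, 1] = 50.0  # slice 1 constant too, but nonzero
        stack = DwiStack(vols, [0.0], (1, 1, 1))
        with pytest.warns(UserWarning, match="empty foreground"):
            report = preprocess.detect_signal_dropout(stack)
        assert all(stack.excluded[0, :, 0])

    def test_report_entries_consistent(self):
        stack = _stack_with_scales([1.0, 1.0, 0.4])
        report = preprocess.detect_signal_dropout(stack)
        e = report.entries.dropna()
        assert ((e.mean_foreground_signal < e.threshold) == e.excluded).all()


class TestRegistration:
    @pytest.fixture
    def smooth_image(self, rng):
        return gaussian_filter(rng.random((40, 40)), 2.0)

    def test_identity_gives_zero_shift(self, smooth_image):
        est = preprocess.estimate_shift(smooth_image, smooth_image)
        np.testing.assert_allclose(est, 0.0, atol=1e-9)

    @pytest.mark.parametrize("true_shift", [(2.0, -3.0), (1.5, 0.0),
                                            (-0.5, 2.5)])
    def test_known_shift_recovered_2d(self, smooth_image, true_shift):
        moved = nd_shift(smooth_image, true_shift, order=1, mode="nearest")
        est = preprocess.estimate_shift(moved, smooth_image)
        assert np.max(np.abs(est - np.array(true_shift))) < 0.25

    def test_known_shift_recovered_3d(self, rng):
        vol = gaussian_filter(rng.random((16, 20, 20)), 2.0)
        for true_shift in [(0.0, 0.0, 1.0), (1.0, -1.5, 0.5)]:
            moved = nd_shift(vol, true_shift, order=1, mode="nearest")
            est = preprocess.estimate_shift(moved, vol)
            assert np.max(np.abs(est - np.array(true_shift))) < 0.25

    def test_constant_image_warns_zero_shift(self):
        img = np.full((10, 10), 2.0)
        with pytest.warns(UserWarning, match="constant"):
            est = preprocess.estimate_shift(img, np.ones((10, 10)))
        np.testing.assert_array_equal(est, 0.0)

    def test_inplane_correction_recovers_injected_shift(self):
        stack, truth = simulate.make_dwi_phantom(
            noise_sigma=5.0,
            shift_spec=[{"b_index": 0, "repetition": 1, "z": 2,
                         "shift": (2.0, -3.0)}],
            seed=5)
        _, log = preprocess.inplane_motion_correct(stack)
        row = log[(log.b_index == 0) & (log.repetition == 1) & (log.z == 2)]
        est = row[["shift_y", "shift_x"]].to_numpy()[0]
        assert np.max(np.abs(est - np.array([2.0, -3.0]))) < 0.25
        others = log.drop(row.index)
        assert np.abs(others[["shift_y", "shift_x"]].to_numpy()).max() < 0.25

    def test_unshifted_stack_all_zero_shifts(self):
        stack, _ = simulate.make_dwi_phantom(noise_sigma=0.0, seed=1)
        _, log = preprocess.inplane_motion_correct(stack)
        assert np.abs(log[["shift_y", "shift_x"]].to_numpy()).max() < 1e-6

    def test_volume_correction_static_and_shifted(self):
        series, (tumor, aorta), _ = simulate.make_dce_phantom(seed=2)
        corrected, log = preprocess.volume_motion_correct(series, 5)
        assert np.abs(log[["shift_z", "shift_y", "shift_x"]].to_numpy()).max() \
            < 0.25
        # inject a known 3-D shift into one frame
        series2 = series.copy()
        series2.frames[50] = nd_shift(series.frames[50], (0, 0, 1.0),
                                      order=1, mode="nearest")
        _, log2 = preprocess.volume_motion_correct(series2, 5)
        est = log2.loc[50, ["shift_z", "shift_y", "shift_x"]].to_numpy()
        assert np.max(np.abs(est - np.array([0, 0, 1.0]))) < 0.25

    def test_enhancement_only_change_is_not_motion(self):
        # bolus enhancement alone must not look like a shift
        series, _, _ = simulate.make_dce_phantom(noise_sd=1.0, seed=3)
        _, log = preprocess.volume_motion_correct(series, 5)
        assert np.abs(log[["shift_z", "shift_y", "shift_x"]].to_numpy()).max() \
            <= 0.5


class TestAverageRepetitions:
    def test_identical_repetitions_average_to_themselves(self):
        stack = _stack_with_scales([1.0] * 4)
        grids, counts = preprocess.average_repetitions(stack)
        np.testing.assert_allclose(grids[0].data[0], stack.volumes[0, 0, 0])
        assert (counts == 4).all()

    def test_excluded_dropout_left_out_of_mean(self):
        stack = _stack_with_scales([1.0, 1.0, 1.0, 0.4])
        preprocess.detect_signal_dropout(stack)
        grids, counts = preprocess.average_repetitions(stack)
        expected = stack.volumes[0, :3, 0].mean(axis=0)  # direct arithmetic
        np.testing.assert_allclose(grids[0].data[0], expected)
        assert counts[0, 0] == 3

    def test_all_excluded_slice_becomes_nan(self):
        stack = _stack_with_scales([1.0, 1.0])
        stack.excluded[0, :, 0] = True
        with pytest.warns(UserWarning, match="all repetitions excluded"):
            grids, counts = preprocess.average_repetitions(stack)
        assert np.isnan(grids[0].data[0]).all()
        assert counts[0, 0] == 0
        assert counts[1, 0] == 2
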