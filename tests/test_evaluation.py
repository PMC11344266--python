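"""Masked metrics, SSIM, distance stratification, ADC, rank tests."""

import numpy as np
import pytest
from skimage.metrics import structural_similarity

from dwifov.core_io import DWIStudy, GradientTable
from dwifov.evaluation import (adc_map, compare_methods, direction_bias_test,
                               distance_stratified_metrics,
                               evaluate_imputation, masked_mse, masked_psnr,
                               ssim_3d)
from dwifov.normalization import BrainMask, FOVMask
from dwifov.phantom import tensor_signal

from conftest import random_study


class TestMaskedMSEPSNR:
    def test_identical_volumes(self, rng):
        x = rng.uniform(size=(6, 6, 6))
        m = np.ones_like(x, dtype=bool)
        assert masked_mse(x, x, m) == 0.0
        assert masked_psnr(x, x, m) == float("inf")

    def test_constant_difference(self):
        a = np.zeros((5, 5, 5))
        b = np.full((5, 5, 5), 0.1)
        m = np.ones((5, 5, 5), dtype=bool)
        assert masked_mse(a, b, m) == pytest.approx(0.01, abs=1e-15)

    @pytest.mark.parametrize("mse,db", [(0.01, 20.0), (0.001, 30.0)])
    def test_psnr_analytic_values(self, mse, db):
        a = np.zeros((4, 4, 4))
        b = np.full((4, 4, 4), np.sqrt(mse))
        m = np.ones((4, 4, 4), dtype=bool)
        assert masked_psnr(a, b, m, data_range=1.0) == \
            pytest.approx(db, abs=1e-9)

    def test_matches_voxel_loop_oracle_on_random_fixtures(self):
        for trial in range(20):
            rng = np.random.default_rng(trial)
            a = rng.uniform(size=(5, 5, 5))
            b = rng.uniform(size=(5, 5, 5))
            m = rng.random((5, 5, 5)) < 0.6
            m[2, 2, 2] = True
            total, count = 0.0, 0
            for idx in np.ndindex(5, 5, 5):
                if m[idx]:
                    total += (a[idx] - b[idx]) ** 2
                    count += 1
            assert masked_mse(a, b, m) == pytest.approx(total / count,
                                                        abs=1e-10)

    def test_mask_permutation_invariance(self, rng):
        a = rng.uniform(size=(4, 4, 4))
        b = rng.uniform(size=(4, 4, 4))
        m = rng.random((4, 4, 4)) < 0.5
        m[0, 0, 0] = True
        # permuting voxel order inside the mask leaves the value unchanged
        perm = rng.permutation(int(m.sum()))
        a2, b2 = a.copy(), b.copy()
        a2[m] = a[m][perm]
        b2[m] = b[m][perm]
        assert masked_mse(a, b, m) == pytest.approx(masked_mse(a2, b2, m))

    def test_empty_mask_rejected(self, rng):
        x = rng.uniform(size=(4, 4, 4))
        with pytest.raises(ValueError):
            masked_mse(x, x, np.zeros((4, 4, 4), dtype=bool))


def naive_ssim(a, b, window=7, data_range=1.0):
    """Brute-force sliding-window SSIM (valid windows, uniform weights)."""
    pad = window // 2
    c1 = (0.01 * data_range) ** 2
    c2 = (0.03 * data_range) ** 2
    npix = window ** a.ndim
    vals = np.zeros(tuple(s - 2 * pad for s in a.shape))
    for idx in np.ndindex(vals.shape):
        sl = tuple(slice(i, i + window) for i in idx)
        pa, pb = a[sl].ravel(), b[sl].ravel()
        ua, ub = pa.mean(), pb.mean()
        va = ((pa - ua) ** 2).sum() / (npix - 1)
        vb = ((pb - ub) ** 2).sum() / (npix - 1)
        cov = ((pa - ua) * (pb - ub)).sum() / (npix - 1)
        vals[idx] = ((2 * ua * ub + c1) * (2 * cov + c2)
                     / ((ua ** 2 + ub ** 2 + c1) * (va + vb + c2)))
    return vals


class TestSSIM:
    def test_identity_is_one(self, rng):
        x = rng.uniform(size=(9, 9, 9))
        assert ssim_3d(x, x) == pytest.approx(1.0, abs=1e-12)

    def test_anticorrelated_pair_is_negative(self, rng):
        x = rng.uniform(size=(10, 10, 10))
        mirrored = 2 * x.mean() - x      # reflect about the global mean
        assert ssim_3d(x, mirrored) < 0

    def test_matches_naive_sliding_window_oracle(self):
        rng = np.random.default_rng(5)
        a = rng.uniform(size=(9, 9, 9))
        b = np.clip(a + rng.normal(0, 0.1, a.shape), 0, 1)
        mine = ssim_3d(a, b, window=7)
        oracle = naive_ssim(a, b, window=7).mean()
        assert mine == pytest.approx(oracle, abs=1e-6)

    def test_cross_check_against_skimage(self, rng):
        a = rng.uniform(size=(12, 12, 12))
        b = np.clip(a + rng.normal(0, 0.05, a.shape), 0, 1)
        mine = ssim_3d(a, b, window=7, data_range=1.0)
        ref = structural_similarity(a, b, win_size=7, data_range=1.0,
                                    gaussian_weights=False)
        assert mine == pytest.approx(ref, abs=1e-6)

    def test_too_small_volume_rejected(self, rng):
        x = rng.uniform(size=(5, 5, 5))
        with pytest.raises(ValueError):
            ssim_3d(x, x, window=7)
        with pytest.raises(ValueError):
            ssim_3d(x, x, window=4)


def _fov_missing_top(shape, k):
    mask = np.ones(shape, dtype=np.uint8)
    mask[:, :, -k:] = 1
    mask[:, :, shape[2] - k:] = 0
    return FOVMask(mask, "top", float(k))


class TestDistanceStratified:
    def _setup(self, rng, shape=(12, 12, 20), k=5):
        brain = BrainMask(np.ones(shape, dtype=np.uint8))
        fov = _fov_missing_top(shape, k)
        ref = rng.uniform(size=shape)
        return ref, fov, brain

    def test_one_slice_per_millimetre_bin(self, rng):
        ref, fov, brain = self._setup(rng)
        table = distance_stratified_metrics(ref, ref + 0.01, fov, brain,
                                            voxel_size=1.0)
        np.testing.assert_array_equal(table.distance_mm,
                                      [1.0, 2.0, 3.0, 4.0, 5.0])
        assert (table.n_slices == 1).all()

    def test_perfect_prediction_gives_sentinels(self, rng):
        ref, fov, brain = self._setup(rng)
        table = distance_stratified_metrics(ref, ref.copy(), fov, brain)
        assert np.isinf(table.psnr).all()
        np.testing.assert_allclose(table.ssim, 1.0, atol=1e-12)

    def test_linearly_growing_error_gives_decreasing_psnr(self, rng):
        ref, fov, brain = self._setup(rng)
        test = ref.copy()
        for z, d in zip(range(15, 20), range(1, 6)):
            test[:, :, z] += 0.02 * d    # error grows with distance
        table = distance_stratified_metrics(ref, test, fov, brain)
        assert (np.diff(table.psnr) < 0).all()

    def test_no_missing_slices_rejected(self, rng):
        ref = rng.uniform(size=(10, 10, 10))
        brain = BrainMask(np.ones((10, 10, 10), dtype=np.uint8))
        with pytest.raises(ValueError):
            distance_stratified_metrics(
                ref, ref, FOVMask.all_acquired((10, 10, 10)), brain)


def _tensor_study(rng, D, b=1300.0, n_dirs=6, shape=(6, 6, 6)):
    from dwifov.phantom import fibonacci_directions
    bvals = np.concatenate([[0.0], np.full(n_dirs, b)])
    bvecs = np.concatenate([np.zeros((1, 3)), fibonacci_directions(n_dirs)])
    s0 = np.full(shape, 1.0)
    tensors = np.broadcast_to(D, shape + (3, 3)).copy()
    data = tensor_signal(s0, tensors, bvals, bvecs)
    return DWIStudy(data, GradientTable(bvals, bvecs), (1, 1, 1), np.eye(4)), \
        tensors, bvecs


class TestADC:
    def test_isotropic_analytic_value(self, rng):
        study, _, _ = _tensor_study(rng, 1.0e-3 * np.eye(3))
        # S/S0 = exp(−1.3) -> ADC = 1.0e−3 mm²/s in every direction
        for d in range(6):
            np.testing.assert_allclose(adc_map(study, d), 1.0e-3, atol=1e-12)

    def test_equal_signal_gives_zero(self):
        bvals = np.array([0.0, 1300.0])
        bvecs = np.array([[0, 0, 0], [1, 0, 0.0]])
        data = np.ones((4, 4, 4, 2))
        study = DWIStudy(data, GradientTable(bvals, bvecs), (1, 1, 1),
                         np.eye(4))
        np.testing.assert_array_equal(adc_map(study, 0), 0.0)

    def test_recovers_quadratic_form_of_anisotropic_tensor(self, rng):
        D = np.diag([1.7e-3, 0.2e-3, 0.2e-3])
        study, tensors, bvecs = _tensor_study(rng, D)
        for d in range(6):
            g = bvecs[d + 1]
            expected = g @ D @ g
            np.testing.assert_allclose(adc_map(study, d), expected,
                                       atol=1e-8)

    def test_nonpositive_signal_marked_invalid(self):
        bvals = np.array([0.0, 1300.0])
        bvecs = np.array([[0, 0, 0], [1, 0, 0.0]])
        data = np.ones((2, 2, 2, 2))
        data[0, 0, 0, 1] = 0.0
        study = DWIStudy(data, GradientTable(bvals, bvecs), (1, 1, 1),
                         np.eye(4))
        adc = adc_map(study, 0)
        assert np.isnan(adc[0, 0, 0]) and np.isfinite(adc[1, 1, 1])

    def test_no_b0_rejected(self, rng):
        study = random_study(rng, n_b0=0, n_weighted=2)
        with pytest.raises(ValueError):
            adc_map(study, 0)


def kruskal_oracle(groups):
    """Independent rank-sum Kruskal–Wallis H with tie correction."""
    pooled = np.concatenate(groups)
    order = np.argsort(pooled, kind="mergesort")
    ranks = np.empty(len(pooled))
    sorted_vals = pooled[order]
    i = 0
    while i < len(pooled):
        j = i
        while j + 1 < len(pooled) and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        ranks[order[i:j + 1]] = (i + j) / 2 + 1
        i = j + 1
    n = len(pooled)
    start, h = 0, 0.0
    for g in groups:
        r = ranks[start:start + len(g)]
        h += r.sum() ** 2 / len(g)
        start += len(g)
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    _, counts = np.unique(pooled, return_counts=True)
    tie = 1 - (counts ** 3 - counts).sum() / (n ** 3 - n)
    return h / tie


class TestDirectionBias:
    def test_identical_groups_degenerate(self):
        h, p = direction_bias_test([[1.0, 1.0], [1.0, 1.0]])
        assert h == 0.0 and p == 1.0

    def test_separated_groups_significant(self):
        _, p = direction_bias_test([[1, 2, 3], [100, 101, 102]])
        assert p < 0.05

    def test_matches_rank_sum_oracle(self):
        for trial in range(10):
            rng = np.random.default_rng(trial)
            groups = [rng.normal(size=rng.integers(3, 8)) for _ in range(4)]
            h, _ = direction_bias_test(groups)
            assert h == pytest.approx(kruskal_oracle(groups), abs=1e-9)

    def test_too_few_groups_rejected(self):
        with pytest.raises(ValueError):
            direction_bias_test([[1.0, 2.0]])


class TestCompareMethods:
    def _inputs(self, rng):
        ref = random_study(rng, shape=(10, 10, 12))
        fov = _fov_missing_top((10, 10, 12), 3)
        brain = BrainMask(np.ones((10, 10, 12), dtype=np.uint8))
        return ref, fov, brain

    def test_copy_reference_method_is_perfect(self, rng):
        ref, fov, brain = self._inputs(rng)
        df = compare_methods({0: ref}, {"copy": {0: ref}}, {0: fov},
                             {0: brain})
        assert np.isinf(df.psnr_mean).all()
        np.testing.assert_allclose(df.ssim_mean, 1.0, atol=1e-12)

    def test_single_row_composes_metric_ops(self, rng):
        ref, fov, brain = self._inputs(rng)
        test = ref.with_data(
            np.clip(ref.data + rng.normal(0, 0.05, ref.data.shape),
                    0, None).astype(np.float32))
        df = compare_methods({0: ref}, {"m": {0: test}}, {0: fov},
                             {0: brain})
        direct = evaluate_imputation(ref, test, fov, brain)
        for group in ("b0", "bweighted"):
            row = df[df.shell_group == group].iloc[0]
            assert row.mse_mean == pytest.approx(direct[group]["mse"])
            assert row.psnr_mean == pytest.approx(direct[group]["psnr"])

    def test_noisier_method_has_lower_psnr(self, rng):
        ref, fov, brain = self._inputs(rng)

        def noisy(scale):
            return ref.with_data(
                np.clip(ref.data + rng.normal(0, scale, ref.data.shape),
                        0, None).astype(np.float32))

        df = compare_methods({0: ref},
                             {"mild": {0: noisy(0.02)},
                              "harsh": {0: noisy(0.2)}},
                             {0: fov}, {0: brain})
        for group in ("b0", "bweighted"):
            sub = df[df.shell_group == group].set_index("method")
            assert sub.loc["mild", "psnr_mean"] > sub.loc["harsh",
                                                          "psnr_mean"]

    def test_key_mismatch_rejected(self, rng):
        ref, fov, brain = self._inputs(rng)
        with pytest.raises(ValueError):
            compare_methods({0: ref}, {"m": {1: ref}}, {0: fov}, {0: brain})
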