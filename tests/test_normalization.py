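"""Normalization, brain masking, cutoff simulation, recombination."""

import numpy as np
import pytest

from dwifov.errors import MaskingError
from dwifov.normalization import (BrainMask, FOVMask, apply_normalization,
                                  compute_brain_mask, compute_normalization,
                                  recombine, simulate_cutoff, slices_for_cut)

from conftest import random_study


def sort_percentile(values, q):
    """Independent sort-based percentile with linear interpolation."""
    v = np.sort(np.asarray(values).ravel())
    pos = q / 100.0 * (len(v) - 1)
    lo, hi = int(np.floor(pos)), int(np.ceil(pos))
    frac = pos - lo
    return v[lo] * (1 - frac) + v[hi] * frac


class TestNormalization:
    def test_constant_study_scale(self, rng):
        study = random_study(rng, shape=(4, 4, 4))
        study.data[:] = 7.0
        assert compute_normalization(study).scale == 7.0

    def test_percentile_matches_sort_oracle(self):
        data = np.arange(1000, dtype=float).reshape(10, 10, 10)[..., None]
        study_scale = compute_normalization(data).scale
        assert study_scale == pytest.approx(sort_percentile(data, 99.9),
                                            abs=1e-9)

    def test_scale_shared_across_volumes(self, rng):
        data = np.stack([rng.uniform(0, 1, (6, 6, 6)),
                         rng.uniform(0, 10, (6, 6, 6))], axis=-1)
        params = compute_normalization(data)
        # the shared scale is driven by the brighter volume, so the dim
        # volume maps well below 1
        assert params.scale == pytest.approx(sort_percentile(data, 99.9))
        assert apply_normalization(data[..., 0], params).max() < 0.5

    def test_order_invariance(self, rng):
        data = rng.uniform(0, 5, (5, 5, 5, 4))
        flipped = data[..., ::-1]
        assert compute_normalization(data).scale == \
            compute_normalization(flipped).scale

    def test_all_zero_study_rejected(self):
        with pytest.raises(ValueError):
            compute_normalization(np.zeros((4, 4, 4, 1)))

    @pytest.mark.parametrize("value,expected",
                             [(10.0, 1.0), (-3.0, 0.0), (20.0, 1.0),
                              (5.0, 0.5)])
    def test_clamping(self, value, expected):
        params = compute_normalization(np.full((4, 4, 4, 1), 10.0))
        out = apply_normalization(np.full((2, 2, 2), value), params)
        assert np.all(out == expected)

    def test_output_always_in_unit_interval(self, rng):
        data = rng.normal(0, 100, (6, 6, 6, 2))
        data[0, 0, 0, 0] = 5.0   # ensure a positive scale
        params = compute_normalization(np.abs(data))
        out = apply_normalization(data, params)
        assert out.min() >= 0.0 and out.max() <= 1.0


class TestBrainMask:
    def _ellipsoid(self, shape=(24, 24, 24), semi=(8, 9, 7)):
        c = (np.asarray(shape) - 1) / 2
        idx = np.stack(np.meshgrid(*[np.arange(s) for s in shape],
                                   indexing="ij"), axis=-1)
        r = np.sqrt((((idx - c) / np.asarray(semi)) ** 2).sum(-1))
        return (r <= 1).astype(float)

    def test_perfect_contrast_recovers_support(self):
        truth = self._ellipsoid()
        mask = compute_brain_mask(truth).mask.astype(bool)
        from scipy import ndimage
        band = ndimage.binary_dilation(truth > 0, iterations=2)
        core = ndimage.binary_erosion(truth > 0, iterations=2)
        assert np.all(mask[core])          # interior always captured
        assert not np.any(mask & ~band)    # nothing beyond 2-voxel band

    def test_noisy_ellipsoid_volume_within_ten_percent(self, rng):
        truth = self._ellipsoid()
        noisy = truth + rng.normal(0, 0.05, truth.shape)
        mask = compute_brain_mask(noisy).mask
        assert abs(mask.sum() - truth.sum()) / truth.sum() < 0.10

    def test_constant_volume_fails(self):
        with pytest.raises(MaskingError):
            compute_brain_mask(np.ones((8, 8, 8)))


def _box_brain(shape=(20, 20, 50), z_lo=10, z_hi=40):
    mask = np.zeros(shape, dtype=np.uint8)
    mask[5:15, 5:15, z_lo:z_hi + 1] = 1
    return BrainMask(mask)


class TestSimulateCutoff:
    def test_zero_cut_is_identity(self, rng):
        data = rng.uniform(size=(20, 20, 50, 2)).astype(np.float32)
        out, fov = simulate_cutoff(data, _box_brain(), 0.0, "top",
                                   voxel_size=1.0)
        np.testing.assert_array_equal(out, data)
        assert fov.mask.all()

    def test_top_cut_removes_slices_adjacent_to_superior_boundary(self, rng):
        data = rng.uniform(size=(20, 20, 50)) + 1.0
        out, fov = simulate_cutoff(data, _box_brain(z_lo=10, z_hi=40), 5.0,
                                   "top", voxel_size=1.0)
        assert np.all(out[:, :, 36:41] == 0)
        assert np.all(out[:, :, :36] == data[:, :, :36])
        assert np.all(out[:, :, 41:] == data[:, :, 41:])
        np.testing.assert_array_equal(fov.missing_z_slices(),
                                      np.arange(36, 41))

    def test_cut_beyond_brain_extent_rejected(self, rng):
        data = rng.uniform(size=(20, 20, 50))
        with pytest.raises(ValueError, match="exceeds brain extent"):
            simulate_cutoff(data, _box_brain(), 45.0, "bottom",
                            voxel_size=1.0)

    def test_random_draws_match_slice_arithmetic(self):
        rng = np.random.default_rng(42)
        brain = _box_brain(z_lo=8, z_hi=44)
        data = np.ones((20, 20, 50))
        for _ in range(100):
            cut = float(rng.uniform(0, 12))
            side = "top" if rng.random() < 0.5 else "bottom"
            _, fov = simulate_cutoff(data, brain, cut, side, voxel_size=1.0)
            k = int(np.floor(cut + 0.5))
            missing = fov.missing_z_slices()
            assert len(missing) == k
            if k:
                if side == "top":
                    assert missing[-1] == 44
                else:
                    assert missing[0] == 8
                assert np.all(np.diff(missing) == 1)

    def test_idempotent_for_fixed_parameters(self, rng):
        data = rng.uniform(size=(20, 20, 50))
        brain = _box_brain()
        once, fov1 = simulate_cutoff(data, brain, 7.0, "bottom",
                                     voxel_size=1.0)
        twice, fov2 = simulate_cutoff(once, brain, 7.0, "bottom",
                                      voxel_size=1.0)
        np.testing.assert_array_equal(once, twice)
        np.testing.assert_array_equal(fov1.mask, fov2.mask)

    @pytest.mark.parametrize("mm,vs,k", [(2.5, 1.0, 3), (4.4, 1.0, 4),
                                         (5.0, 2.0, 3), (0.4, 1.0, 0)])
    def test_slice_count_rounds_half_away_from_zero(self, mm, vs, k):
        assert slices_for_cut(mm, vs) == k


class TestRecombine:
    def test_all_acquired_returns_acquired(self, rng):
        a = rng.uniform(size=(6, 6, 6))
        b = rng.uniform(size=(6, 6, 6))
        fov = FOVMask.all_acquired((6, 6, 6))
        np.testing.assert_array_equal(recombine(a, b, fov), a)

    def test_all_missing_returns_imputed(self, rng):
        a = rng.uniform(size=(6, 6, 6))
        b = rng.uniform(size=(6, 6, 6))
        fov = FOVMask(np.zeros((6, 6, 6)), "none", 0.0)
        np.testing.assert_array_equal(recombine(a, b, fov), b)

    def test_matches_voxel_loop_oracle(self, rng):
        a = rng.uniform(size=(5, 5, 5))
        b = rng.uniform(size=(5, 5, 5))
        m = (rng.random((5, 5, 5)) < 0.5).astype(np.uint8)
        out = recombine(a, b, FOVMask(m, "none", 0.0))
        for idx in np.ndindex(5, 5, 5):
            assert out[idx] == (a[idx] if m[idx] else b[idx])

    def test_acquired_voxels_bit_identical(self, rng):
        a = rng.uniform(size=(6, 6, 6, 3)).astype(np.float32)
        b = rng.uniform(size=(6, 6, 6, 3)).astype(np.float32)
        m = (rng.random((6, 6, 6)) < 0.7).astype(np.uint8)
        out = recombine(a, b, FOVMask(m, "none", 0.0))
        sel = m.astype(bool)
        assert np.array_equal(out[sel].view(np.uint32),
                              a[sel].view(np.uint32))

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            recombine(np.zeros((4, 4, 4)), np.zeros((4, 4, 5)),
                      FOVMask.all_acquired((4, 4, 4)))
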