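"""Per-view prediction plumbing, view merging, end-to-end imputation."""

import numpy as np
import pytest

from dwifov import _autograd as ag
from dwifov.errors import ConfigurationError
from dwifov.gan import ModelBundle
from dwifov.inference import (derive_fov_mask, impute_study, merge_views,
                              predict_volume_view)
from dwifov.normalization import FOVMask, simulate_cutoff


class IdentityGenerator:
    """Oracle generator returning the central DWI input channel."""

    def __init__(self, n=1):
        self.n = n
        self.in_channels = 2 * (2 * n + 1)

    def __call__(self, x):
        return ag.Tensor(x.data[:, self.n:self.n + 1])


class StructuralCopyGenerator:
    """Oracle generator returning the central structural channel."""

    def __init__(self, n=1):
        self.n = n
        self.in_channels = 2 * (2 * n + 1)

    def __call__(self, x):
        c = (2 * self.n + 1) + self.n
        return ag.Tensor(x.data[:, c:c + 1])


class ConstantGenerator:
    """Oracle generator with a fixed output value (normalized scale)."""

    def __init__(self, value, n=1):
        self.n = n
        self.in_channels = 2 * (2 * n + 1)
        self._internal = 2.0 * value - 1.0

    def __call__(self, x):
        return ag.Tensor(np.full((x.data.shape[0], 1) + x.data.shape[2:],
                                 self._internal, dtype=np.float32))


class TestPredictVolumeView:
    def test_identity_generator_reproduces_input_volume(self, rng):
        vol = rng.uniform(0.1, 0.9, size=(12, 12, 12)).astype(np.float32)
        t1 = rng.uniform(size=(12, 12, 12)).astype(np.float32)
        for view in ("sagittal", "coronal"):
            pred = predict_volume_view(IdentityGenerator(), vol, t1, view, 1)
            np.testing.assert_allclose(pred, vol, atol=1e-6)

    def test_constant_generator_gives_constant_volume(self, rng):
        vol = rng.uniform(size=(10, 10, 10)).astype(np.float32)
        pred = predict_volume_view(ConstantGenerator(0.25), vol, vol,
                                   "sagittal", 1)
        np.testing.assert_allclose(pred, 0.25, atol=1e-6)

    def test_every_slice_along_view_axis_assembled(self, rng):
        vol = rng.uniform(0.2, 0.8, size=(9, 9, 9)).astype(np.float32)
        pred = predict_volume_view(ConstantGenerator(0.5), vol, vol,
                                   "coronal", 1)
        assert pred.shape == vol.shape
        assert np.all(pred[:, :, :] > 0)   # all 9 coronal slices filled

    def test_wrong_n_for_generator_rejected(self, rng):
        vol = rng.uniform(size=(8, 8, 8)).astype(np.float32)
        with pytest.raises(ValueError):
            predict_volume_view(IdentityGenerator(n=2), vol, vol,
                                "sagittal", 1)


class TestMergeViews:
    def test_identical_inputs_unchanged(self, rng):
        x = rng.uniform(size=(6, 6, 6))
        np.testing.assert_array_equal(merge_views(x, x), x)

    def test_midpoint_of_zero_and_double(self, rng):
        x = rng.uniform(size=(6, 6, 6))
        np.testing.assert_allclose(merge_views(np.zeros_like(x), 2 * x), x,
                                   atol=1e-12)

    def test_matches_elementwise_mean_oracle(self, rng):
        a = rng.uniform(size=(4, 4, 4))
        b = rng.uniform(size=(4, 4, 4))
        out = merge_views(a, b)
        for idx in np.ndindex(4, 4, 4):
            assert out[idx] == pytest.approx((a[idx] + b[idx]) / 2,
                                             abs=1e-7)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            merge_views(np.zeros((4, 4, 4)), np.zeros((4, 4, 5)))


def _oracle_bundle(n=1):
    bundle = ModelBundle()
    for group in ("b0", "bweighted"):
        for view in ("sagittal", "coronal"):
            bundle.add(group, view, IdentityGenerator(n))
    return bundle


class TestImputeStudy:
    def test_full_fov_changes_no_voxels(self, small_phantom):
        study, t1, brain, _ = small_phantom
        fov = FOVMask.all_acquired(study.shape)
        out, _ = impute_study(_oracle_bundle(), study, t1, fov=fov,
                              brain=brain, n=1)
        assert np.array_equal(out.data.view(np.uint32),
                              study.data.view(np.uint32))

    def test_missing_region_filled_and_rest_untouched(self, small_phantom):
        study, t1, brain, _ = small_phantom
        truncated, fov = simulate_cutoff(study, brain, 5.0, "top")
        # a structural-copy oracle writes nonzero intensities into the
        # missing band (an identity oracle would just reproduce the zeros)
        bundle = ModelBundle()
        for group in ("b0", "bweighted"):
            for view in ("sagittal", "coronal"):
                bundle.add(group, view, StructuralCopyGenerator(1))
        out, _ = impute_study(bundle, truncated, t1, fov=fov, brain=brain,
                              n=1)
        changed = np.any(out.data != truncated.data, axis=3)
        missing = ~fov.mask.astype(bool)
        # voxel-difference support lies exactly inside 1 − m
        assert np.all(missing[changed])
        # at least some brain voxels in the missing band were filled in
        assert np.any(changed & brain.mask.astype(bool))
        acquired = fov.mask.astype(bool)
        assert np.array_equal(out.data[acquired].view(np.uint32),
                              truncated.data[acquired].view(np.uint32))

    def test_gradient_table_copied_unchanged(self, small_phantom):
        study, t1, brain, _ = small_phantom
        truncated, fov = simulate_cutoff(study, brain, 4.0, "bottom")
        out, _ = impute_study(_oracle_bundle(), truncated, t1, fov=fov,
                              brain=brain, n=1)
        assert out.gradients is truncated.gradients
        np.testing.assert_array_equal(out.gradients.bvals,
                                      study.gradients.bvals)

    def test_imputation_is_deterministic(self, small_phantom):
        study, t1, brain, _ = small_phantom
        truncated, fov = simulate_cutoff(study, brain, 5.0, "top")
        a, _ = impute_study(_oracle_bundle(), truncated, t1, fov=fov,
                            brain=brain, n=1)
        b, _ = impute_study(_oracle_bundle(), truncated, t1, fov=fov,
                            brain=brain, n=1)
        assert np.array_equal(a.data.view(np.uint32),
                              b.data.view(np.uint32))

    def test_incomplete_bundle_rejected(self, small_phantom):
        study, t1, brain, _ = small_phantom
        bundle = ModelBundle()
        bundle.add("b0", "sagittal", IdentityGenerator())
        with pytest.raises(ConfigurationError):
            impute_study(bundle, study, t1, brain=brain, n=1)


class TestDeriveFovMask:
    def test_detects_top_truncation(self, small_phantom):
        study, _, brain, _ = small_phantom
        truncated, fov_true = simulate_cutoff(study, brain, 6.0, "top")
        derived = derive_fov_mask(truncated.data, brain)
        assert derived.cut_side == "top"
        np.testing.assert_array_equal(derived.missing_z_slices(),
                                      fov_true.missing_z_slices())

    def test_detects_bottom_truncation(self, small_phantom):
        study, _, brain, _ = small_phantom
        truncated, fov_true = simulate_cutoff(study, brain, 4.0, "bottom")
        derived = derive_fov_mask(truncated.data, brain)
        assert derived.cut_side == "bottom"
        np.testing.assert_array_equal(derived.missing_z_slices(),
                                      fov_true.missing_z_slices())

    def test_complete_fov_gives_all_acquired(self, small_phantom):
        study, _, brain, _ = small_phantom
        derived = derive_fov_mask(study.data, brain)
        assert derived.cut_side == "none"
        assert derived.mask.all()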