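import numpy as np
import pytest

from flimstain.coregister import (AffineTransform, apply_affine,
                                  background_mask_from_intensity,
                                  downsample_he, estimate_affine,
                                  estimate_affine_from_points,
                                  extract_patches,
                                  prepare_he_for_registration)
from flimstain.flim_core import clamp_flim, normalise_intensity
from flimstain.phantom import PhantomSpec, degrade_pair, generate_phantom
from flimstain.stain_formats import FormatTag, StainInput


class TestPrepareHE:
    def test_full_range_image_nearly_unchanged(self, rng):
        img = rng.uniform(0, 1, (64, 64, 3))
        out = prepare_he_for_registration(img)
        assert out.min() == 0.0 and out.max() == 1.0

    def test_percentile_stretch_fills_unit_interval(self):
        ramp = np.linspace(0.4, 0.6, 10000).reshape(100, 100)
        rgb = np.stack([ramp] * 3, axis=-1)
        out = prepare_he_for_registration(rgb)
        # 1st/99th percentiles of the ramp map to 0/1, tails clipped
        assert out.min() == 0.0 and out.max() == 1.0
        mid = out[50, 50]
        assert 0.45 < mid < 0.55

    def test_constant_image_is_error(self):
        with pytest.raises(ValueError, match="dynamic range"):
            prepare_he_for_registration(np.full((8, 8, 3), 0.5))


class TestDownsampleHE:
    def test_he_grid_to_flim_grid_shape(self):
        he = np.zeros((1024, 1024, 3))
        out = downsample_he(he, 0.22, 0.455)
        assert out.shape[:2] == (495, 495)

    def test_identity_factor(self, rng):
        he = rng.uniform(0, 1, (32, 32, 3))
        np.testing.assert_array_equal(downsample_he(he, 0.4, 0.4), he)

    def test_constant_preserved(self):
        out = downsample_he(np.full((64, 64, 3), 0.3), 0.22, 0.455)
        np.testing.assert_allclose(out, 0.3, atol=1e-7)

    def test_nonpositive_pixel_size_rejected(self):
        with pytest.raises(ValueError):
            downsample_he(np.zeros((8, 8, 3)), -0.2, 0.455)


class TestAffineTransform:
    def test_singular_matrix_rejected(self):
        with pytest.raises(ValueError, match="singular"):
            AffineTransform(np.array([[1.0, 2.0, 0.0], [2.0, 4.0, 0.0]]))

    def test_json_roundtrip(self, tmp_path):
        t = AffineTransform.from_params(rotation_deg=10, shift=(3, -2),
                                        scale=1.05, center=(16, 16))
        p = tmp_path / "affine.json"
        t.to_json(p)
        back = AffineTransform.from_json(p)
        np.testing.assert_allclose(back.matrix, t.matrix)

    def test_inverse_composition_is_identity(self):
        t = AffineTransform.from_params(rotation_deg=-7, shift=(5, 9),
                                        scale=0.93, center=(10, 20))
        ident = t.compose(t.inverse()).matrix
        np.testing.assert_allclose(ident, AffineTransform.identity().matrix,
                                   atol=1e-10)


class TestApplyAffine:
    def test_identity_is_bit_equal(self, rng):
        img = rng.uniform(0, 1, (16, 16))
        out = apply_affine(img, AffineTransform.identity(), (16, 16))
        np.testing.assert_array_equal(out, img)

    def test_translate_then_untranslate(self, rng):
        img = rng.uniform(0, 1, (32, 32))
        t = AffineTransform.from_params(shift=(4, -3))
        back = apply_affine(apply_affine(img, t, (32, 32)),
                            t.inverse(), (32, 32))
        core = (slice(8, 24), slice(8, 24))  # interior unaffected by border
        np.testing.assert_allclose(back[core], img[core], atol=1e-6)

    def test_90_degree_rotation_moves_marker(self):
        img = np.zeros((9, 9))
        img[1, 4] = 1.0  # marker above centre
        t = AffineTransform.from_params(rotation_deg=90, center=(4, 4))
        out = apply_affine(img, t, (9, 9))
        # (row, col) rotation by +90° about centre maps (1,4) -> (4,1)
        assert out[4, 1] == pytest.approx(1.0, abs=1e-6)
        assert out[1, 4] == pytest.approx(0.0, abs=1e-6)


class TestEstimateAffine:
    def test_self_registration_is_identity(self, phantom_sample):
        fixed = 1.0 - normalise_intensity(clamp_flim(phantom_sample.flim))
        t = estimate_affine(fixed, fixed, init=AffineTransform.identity())
        err = t.corner_error(AffineTransform.identity(), fixed.shape)
        assert err < 0.1

    def test_recovers_known_translation(self, phantom_sample):
        truth = AffineTransform.from_params(shift=(7, -3))
        deg = degrade_pair(phantom_sample, truth)
        moving = prepare_he_for_registration(deg.degraded_he)
        fixed = 1.0 - normalise_intensity(clamp_flim(phantom_sample.flim))
        t = estimate_affine(moving, fixed, init=AffineTransform.identity())
        assert t.corner_error(deg.truth_transform, fixed.shape) < 0.5

    def test_control_point_least_squares(self):
        truth = AffineTransform.from_params(rotation_deg=12, shift=(4, -6),
                                            scale=1.07, center=(50, 50))
        pts = np.array([[0, 0], [0, 99], [99, 0], [99, 99], [30, 60]], float)
        est = estimate_affine_from_points(pts, truth.apply_points(pts))
        np.testing.assert_allclose(est.matrix, truth.matrix, atol=1e-9)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            estimate_affine_from_points(np.zeros((2, 2)), np.zeros((2, 2)))


class TestExtractPatches:
    @staticmethod
    def _stain(h, w, seed=0):
        rng = np.random.default_rng(seed)
        return StainInput(rng.uniform(0, 1, (h, w, 3)), FormatTag.IW_FLIM)

    def test_grid_count_no_background(self):
        si = self._stain(512, 512)
        target = np.zeros((512, 512, 3))
        mask = np.zeros((512, 512), dtype=bool)
        pairs = extract_patches(si, target, mask, 256, 256)
        assert len(pairs) == 4
        assert sorted(p.origin for p in pairs) == [(0, 0), (0, 256),
                                                   (256, 0), (256, 256)]

    def test_background_filter_is_strict(self):
        # quadrants with background fractions 0.50 / 0.75 / 0.76 / 1.00
        si = self._stain(20, 20)
        target = np.zeros((20, 20, 3))
        mask = np.zeros((20, 20), dtype=bool)
        fracs = {(0, 0): 0.50, (0, 10): 0.75, (10, 0): 0.76, (10, 10): 1.00}
        for (r, c), f in fracs.items():
            n_bg = int(round(f * 100))
            flat = np.zeros(100, dtype=bool)
            flat[:n_bg] = True
            mask[r:r + 10, c:c + 10] = flat.reshape(10, 10)
        pairs = extract_patches(si, target, mask, 10, 10)
        kept = sorted(p.origin for p in pairs)
        assert kept == [(0, 0), (0, 10)]  # 0.76 and 1.00 dropped, 0.75 kept

    def test_partial_edge_patches_dropped(self):
        si = self._stain(300, 300)
        pairs = extract_patches(si, np.zeros((300, 300, 3)),
                                np.zeros((300, 300), bool), 256, 256)
        assert len(pairs) == 1

    def test_count_matches_brute_force_and_crops_are_views_of_source(self):
        rng = np.random.default_rng(5)
        si = self._stain(96, 96, seed=5)
        target = rng.uniform(0, 1, (96, 96, 3))
        mask = rng.random((96, 96)) < 0.7
        patch, stride = 32, 16
        pairs = extract_patches(si, target, mask, patch, stride)
        expected = 0
        for r in range(0, 96 - patch + 1, stride):
            for c in range(0, 96 - patch + 1, stride):
                if mask[r:r + patch, c:c + patch].mean() <= 0.75:
                    expected += 1
        assert len(pairs) == expected
        for p in pairs:
            r, c = p.origin
            np.testing.assert_array_equal(
                p.input_patch.pixels, si.pixels[r:r + patch, c:c + patch])
            np.testing.assert_array_equal(
                p.target_patch, target[r:r + patch, c:c + patch])

    def test_patch_larger_than_image_rejected(self):
        si = self._stain(64, 64)
        with pytest.raises(ValueError):
            extract_patches(si, np.zeros((64, 64, 3)),
                            np.zeros((64, 64), bool), 128, 128)

    def test_background_mask_threshold(self):
        norm = np.array([[0.01, 0.04], [0.05, 0.9]])
        np.testing.assert_array_equal(
            background_mask_from_intensity(norm),
            [[True, True], [False, False]])
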