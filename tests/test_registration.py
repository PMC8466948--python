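"""Slice registration: NCC oracle, affine recovery, ΔIm bookkeeping."""

import numpy as np
import pytest
from scipy import ndimage

import trabmorph as tm


@pytest.fixture(scope="module")
def rod_image(rod_phantom_bimodal):
    img, _, _ = rod_phantom_bimodal
    return img


class TestUpscale:
    def test_constant_stays_constant(self):
        img = tm.ImageGrid(np.full((16, 16), 3.5), (0.1, 0.1))
        out = tm.upscale_to_reference(img, (32, 32))
        assert np.allclose(out.values, 3.5)
        assert out.spacing == (0.05, 0.05)

    def test_mean_preserved_through_round_trip(self, rod_image):
        up = tm.upscale_to_reference(rod_image, (320, 320))
        down = up.values.reshape(160, 2, 160, 2).mean(axis=(1, 3))
        assert down.mean() == pytest.approx(rod_image.values.mean(), abs=1e-6)

    def test_linear_ramp_stays_linear(self):
        ramp = np.tile(np.arange(16.0), (16, 1))
        img = tm.ImageGrid(ramp, (0.1, 0.1))
        out = tm.upscale_to_reference(img, (32, 32))
        # bilinear interpolation of a linear function is linear; check
        # constant second differences along the interior of each row
        interior = out.values[:, 2:-2]
        second = np.diff(interior, n=2, axis=1)
        assert np.allclose(second, 0.0, atol=1e-9)
        assert out.values.min() >= ramp.min() - 1e-12
        assert out.values.max() <= ramp.max() + 1e-12

    def test_shrinking_rejected(self, rod_image):
        with pytest.raises(ValueError, match="smaller"):
            tm.upscale_to_reference(rod_image, (80, 80))


class TestNccScore:
    def test_self_correlation_is_one(self, rod_image):
        assert tm.ncc_score(rod_image, rod_image) == pytest.approx(1.0)

    def test_anticorrelation_is_minus_one(self, rod_image):
        neg = tm.ImageGrid(-rod_image.values + 5.0, rod_image.spacing)
        assert tm.ncc_score(rod_image, neg) == pytest.approx(-1.0)

    def test_matches_direct_sum_formula(self):
        rng = np.random.default_rng(21)
        for _ in range(10):
            a = rng.random((64, 64))
            b = rng.random((64, 64))
            am, bm = a - a.mean(), b - b.mean()
            expected = (am * bm).sum() / np.sqrt((am**2).sum() * (bm**2).sum())
            assert tm.ncc_score(a, b) == pytest.approx(expected, abs=1e-10)

    def test_symmetric_and_affine_invariant(self):
        rng = np.random.default_rng(2)
        a, b = rng.random((32, 32)), rng.random((32, 32))
        s = tm.ncc_score(a, b)
        assert tm.ncc_score(b, a) == pytest.approx(s, abs=1e-12)
        assert tm.ncc_score(3.0 * a + 7.0, b) == pytest.approx(s, abs=1e-10)

    def test_flat_image_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            tm.ncc_score(np.ones((8, 8)), np.random.default_rng(0).random((8, 8)))


class TestAffineRegistration:
    def test_identity_recovered(self, rod_image):
        rep, warped = tm.register_affine_multimodal(rod_image, rod_image)
        t_px = np.array(rep.transform[4:]) / 0.05
        a = np.array(rep.transform[:4]).reshape(2, 2)
        rot = np.rad2deg(np.arctan2(a[1, 0], a[0, 0]))
        assert np.all(np.abs(t_px) < 0.5)
        assert abs(rot) < 0.5
        assert tm.ncc_score(warped, rod_image) > 0.99

    def test_translation_recovered_within_1px(self, rod_image):
        moved = tm.ImageGrid(ndimage.shift(rod_image.values, (7, -4),
                                           order=1, mode="nearest"),
                             rod_image.spacing)
        rep, _ = tm.register_affine_multimodal(moved, rod_image)
        t_px = np.array(rep.transform[4:]) / 0.05  # (x=col, y=row)
        assert t_px[0] == pytest.approx(-4.0, abs=1.0)
        assert t_px[1] == pytest.approx(7.0, abs=1.0)

    def test_rotation_recovered_under_modality_change(self, rod_image):
        rot = ndimage.rotate(rod_image.values, 3.0, reshape=False, order=1,
                             mode="nearest")
        rot = ndimage.gaussian_filter(rot, 1.5)
        rot = rot.max() + rot.min() - rot  # invert contrast
        rep, _ = tm.register_affine_multimodal(
            tm.ImageGrid(rot, rod_image.spacing), rod_image)
        a = np.array(rep.transform[:4]).reshape(2, 2)
        angle = np.rad2deg(np.arctan2(a[1, 0], a[0, 0]))
        assert abs(abs(angle) - 3.0) < 1.0


class TestFindBestSlice:
    @pytest.fixture(scope="class")
    def stack(self, rod_image):
        return tm.make_slice_stack(rod_image, 24, 0.05, seed=5)

    def test_exact_probe_recovers_index(self, stack):
        rep = tm.find_best_slice(stack.slice2d(11), stack, 11, n_reg=9,
                                 register=False)
        assert rep.best_index == 11
        assert rep.ncc == pytest.approx(1.0, abs=1e-9)

    def test_degraded_probe_within_one_slice(self, stack):
        d = tm.DegradationSpec(psf_sigma=0.08, downsample_factor=2.6,
                               noise_sigma=0.02, invert_contrast=True,
                               bias_field_amplitude=0.15)
        probe = tm.degrade_to_mri(stack.slice2d(13), d, seed=8)
        rep = tm.find_best_slice(probe, stack, 13, n_reg=9)
        assert abs(rep.best_index - 13) <= 1

    def test_identical_stack_tie_resolves_low(self, rod_image):
        flat = tm.ImageGrid(np.repeat(rod_image.values[None], 6, axis=0),
                            (0.05, 0.05, 0.05))
        rep = tm.find_best_slice(rod_image, flat, 3, n_reg=5, register=False)
        assert np.allclose(rep.ncc_profile, rep.ncc_profile[0])
        assert rep.best_index == rep.candidate_indices[0]

    def test_window_clipped_at_stack_ends(self, stack):
        rep = tm.find_best_slice(stack.slice2d(1), stack, 1, n_reg=9,
                                 register=False)
        assert rep.candidate_indices[0] == 0
        assert rep.best_index == 1


class TestDeltaIm:
    @pytest.mark.parametrize("thickness,expected", [(1.5, 59), (1.0, 39),
                                                    (1.1, 43)])
    def test_published_sequence_geometries(self, thickness, expected):
        g = tm.SequenceGeometry(thickness, thickness, 0.2, 0.05)
        assert tm.expected_delta_im(g) == expected

    def test_shipped_geometry_table(self):
        assert tm.expected_delta_im(tm.SEQUENCE_GEOMETRIES["7T_TSE"]) == 59
        assert tm.expected_delta_im(tm.SEQUENCE_GEOMETRIES["7T_GRE"]) == 39
        assert tm.expected_delta_im(tm.SEQUENCE_GEOMETRIES["3T_TSE"]) == 43
        assert tm.expected_delta_im(tm.SEQUENCE_GEOMETRIES["3T_GRE"]) == 43

    def test_regular_series(self):
        q = tm.delta_im_series([10, 70, 130])
        assert q.delta_im_mean == 59.0
        assert q.delta_im_sd == 0.0

    def test_irregular_series_sample_sd(self):
        q = tm.delta_im_series([10, 70, 132])
        # gaps are exclusive counts: (60-1, 62-1) = (59, 61)
        assert q.gaps == (59, 61)
        assert q.delta_im_mean == 60.0
        assert q.delta_im_sd == pytest.approx(np.sqrt(2.0))

    def test_single_pair_sd_is_nan(self):
        q = tm.delta_im_series([10, 70])
        assert q.delta_im_mean == 59.0
        assert np.isnan(q.delta_im_sd)

    def test_non_monotone_warns_and_uses_absolute(self):
        with pytest.warns(UserWarning, match="monotone"):
            q = tm.delta_im_series([70, 10, 70])
        assert q.gaps == (59, 59)

    def test_indivisible_period_rejected(self):
        g = tm.SequenceGeometry(1.0, 0.03, 0.2, 0.05)
        with pytest.raises(ValueError, match="divide"):
            tm.expected_delta_im(g)
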