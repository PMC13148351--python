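import numpy as np
import pytest
from oracles import ncc_brute

import filmdose as fd
from filmdose.registration import _rotate_template


def _embed(plan_arr, canvas_shape, offset, angle_deg=0.0, rng=None, snr_db=None):
    """Plan pasted into a zero background at a known transform, plus noise."""
    from scipy import ndimage

    arr = plan_arr
    if angle_deg:
        arr = np.clip(
            ndimage.rotate(arr, angle_deg, reshape=False, order=1, mode="constant", cval=0.0),
            0, None,
        )
    canvas = np.zeros(canvas_shape)
    r, c = offset
    canvas[r : r + arr.shape[0], c : c + arr.shape[1]] = arr
    if snr_db is not None:
        sig_rms = np.sqrt((canvas**2).mean())
        canvas = canvas + sig_rms * 10 ** (-snr_db / 20) * rng.standard_normal(canvas_shape)
        canvas = np.clip(canvas, 0, None)
    return canvas


@pytest.fixture(scope="module")
def plan_arr(square_plan):
    return square_plan.dose_gy


class TestPreprocess:
    def test_both_flags_off_is_identity(self):
        arr = np.arange(12.0).reshape(3, 4)
        np.testing.assert_array_equal(fd.preprocess_film(arr, False, False), arr)

    def test_vertical_flip_is_involution(self):
        arr = np.arange(12.0).reshape(3, 4)
        once = fd.preprocess_film(arr, True, False)
        np.testing.assert_array_equal(fd.preprocess_film(once, True, False), arr)

    def test_hand_computed_2x3_bookkeeping(self):
        arr = np.array([[1.0, 2.0, 3.0], [4.0, 5.0, 6.0]])
        flipped = fd.preprocess_film(arr, True, False)
        np.testing.assert_array_equal(flipped, [[4, 5, 6], [1, 2, 3]])
        both = fd.preprocess_film(arr, True, True)
        # flip + 180-degree rotation = mirror about the vertical axis
        np.testing.assert_array_equal(both, [[3, 2, 1], [6, 5, 4]])

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            fd.preprocess_film(np.empty((0, 3)))


class TestNccMap:
    def test_verbatim_subimage_peaks_at_one(self, rng):
        image = rng.random((40, 40))
        template = image[10:26, 7:23]
        score = fd.ncc_map(template, image)
        r, c = np.unravel_index(np.argmax(score), score.shape)
        assert (r, c) == (10, 7)
        assert score[10, 7] == pytest.approx(1.0, abs=1e-12)

    def test_invariance_to_affine_intensity_change(self, rng):
        image = rng.random((32, 32))
        template = 2.0 * image[5:17, 8:20] + 5.0
        score = fd.ncc_map(template, image)
        r, c = np.unravel_index(np.argmax(score), score.shape)
        assert (r, c) == (5, 8)
        assert score[5, 8] == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("tshape,ishape", [((8, 8), (32, 32)), ((5, 9), (20, 25))])
    def test_matches_brute_force_everywhere(self, tshape, ishape, rng):
        template = rng.random(tshape)
        image = rng.random(ishape)
        np.testing.assert_allclose(
            fd.ncc_map(template, image), ncc_brute(template, image), atol=1e-10
        )

    def test_matches_skimage_match_template(self, rng):
        from skimage.feature import match_template as sk_match

        template = rng.random((9, 9))
        image = rng.random((30, 30))
        np.testing.assert_allclose(
            fd.ncc_map(template, image), sk_match(image, template), atol=1e-8
        )

    def test_zero_variance_template_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            fd.ncc_map(np.ones((4, 4)), np.random.default_rng(0).random((10, 10)))

    def test_zero_variance_window_scores_zero(self, rng):
        image = np.zeros((20, 20))
        image[12:18, 12:18] = rng.random((6, 6))
        template = rng.random((4, 4))
        score = fd.ncc_map(template, image)
        assert score[0, 0] == 0.0  # fully uniform window

    def test_values_bounded_by_unity(self, rng):
        score = fd.ncc_map(rng.random((6, 6)), rng.random((25, 25)))
        assert np.abs(score).max() <= 1 + 1e-9


class TestMatchTemplate:
    def test_exact_embedding_recovered(self, square_plan, plan_arr):
        film = fd.DoseMap(
            _embed(plan_arr, (60, 64), (12, 17)), square_plan.pixel_spacing_mm
        )
        res = fd.match_template(square_plan, film)
        assert res.offset_px == (12, 17)
        assert res.angle_deg == 0.0
        assert res.ncc_score == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize("angle", [-3.0, -2.0, 2.0, 3.0])
    def test_rotated_embedding_recovers_angle_and_offset(self, angle, square_plan,
                                                         plan_arr, rng):
        film = fd.DoseMap(
            _embed(plan_arr, (60, 64), (10, 14), angle_deg=angle, rng=rng, snr_db=20),
            square_plan.pixel_spacing_mm,
        )
        res = fd.match_template(square_plan, film)
        assert res.angle_deg == angle
        assert abs(res.offset_px[0] - 10) <= 1
        assert abs(res.offset_px[1] - 14) <= 1

    def test_plan_larger_than_film_rejected(self, square_plan):
        small = fd.DoseMap(np.ones((10, 10)), square_plan.pixel_spacing_mm)
        with pytest.raises(ValueError, match="exceeds"):
            fd.match_template(square_plan, small)

    def test_spacing_mismatch_handled_by_resampling(self, square_plan, plan_arr):
        # film at half the plan's pixel spacing: offsets are in film pixels
        fine = fd.resample_to_grid(square_plan, (1.0, 1.0))
        film = fd.DoseMap(_embed(fine.dose_gy, (110, 120), (20, 30)), (1.0, 1.0))
        res = fd.match_template(square_plan, film)
        assert abs(res.offset_px[0] - 20) <= 1
        assert abs(res.offset_px[1] - 30) <= 1


class TestCropMatched:
    def test_identity_registration_crops_exact_region(self, square_plan, plan_arr):
        film = fd.DoseMap(_embed(plan_arr, (60, 64), (12, 17)), square_plan.pixel_spacing_mm)
        res = fd.match_template(square_plan, film)
        crop = fd.crop_matched(film, res, square_plan.shape)
        np.testing.assert_array_equal(crop.dose_gy, plan_arr)

    def test_crop_of_crop_is_idempotent(self, square_plan, plan_arr):
        film = fd.DoseMap(_embed(plan_arr, (60, 64), (12, 17)), square_plan.pixel_spacing_mm)
        res = fd.match_template(square_plan, film)
        crop = fd.crop_matched(film, res, square_plan.shape)
        res0 = fd.RegistrationResult((0, 0), 0.0, 1.0, np.ones((1, 1)))
        again = fd.crop_matched(crop, res0, square_plan.shape)
        np.testing.assert_array_equal(again.dose_gy, crop.dose_gy)

    def test_rotated_round_trip_recovers_plan(self, square_plan, plan_arr):
        film = fd.DoseMap(
            _embed(plan_arr, (60, 64), (10, 14), angle_deg=2.0),
            square_plan.pixel_spacing_mm,
        )
        res = fd.match_template(square_plan, film)
        crop = fd.crop_matched(film, res, square_plan.shape)
        mean_err = np.abs(crop.dose_gy - plan_arr).mean()
        assert mean_err < 0.02 * plan_arr.max()  # interpolation loss only

    def test_out_of_bounds_crop_rejected(self, square_plan, plan_arr):
        film = fd.DoseMap(_embed(plan_arr, (60, 64), (12, 17)), square_plan.pixel_spacing_mm)
        res = fd.RegistrationResult((50, 50), 0.0, 1.0, np.ones((1, 1)))
        with pytest.raises(ValueError, match="bounds"):
            fd.crop_matched(film, res, square_plan.shape)


class TestRotationFill:
    def test_zero_angle_returns_same_object(self, plan_arr):
        assert _rotate_template(plan_arr, 0.0) is plan_arr

    def test_rotation_preserves_shape(self, plan_arr):
        assert _rotate_template(plan_arr, 2.5).shape == plan_arr.shape
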