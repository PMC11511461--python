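import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pupilgaze import metrics, synthdata
from pupilgaze.gazemap import MappingModel
from pupilgaze.metrics import (
    angular_error,
    cross_validate,
    five_pixel_rate,
    gaze_angles_from_screen,
    localization_error,
    precision,
    rmse,
)

IDENTITY = MappingModel(order=2, A=[0, 1, 0, 0, 0, 0], B=[0, 0, 1, 0, 0, 0])

finite = st.floats(min_value=-1e3, max_value=1e3, allow_nan=False)
nonzero_vec = st.tuples(finite, finite, finite).filter(
    lambda v: math.hypot(*v) > 1e-3
)


class TestFivePixelRate:
    def test_all_below(self):
        assert five_pixel_rate([0, 1, 2, 3, 4]) == 1.0

    def test_strict_inequality(self):
        assert five_pixel_rate([5, 6]) == 0.0

    def test_mixed(self):
        assert five_pixel_rate([4.9, 5.0, 1.0, 10.0]) == 0.5

    def test_nan_excluded_from_denominator(self):
        assert five_pixel_rate([1.0, float("nan"), 10.0]) == 0.5

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            five_pixel_rate([])


class TestPrecision:
    def test_simple(self):
        assert precision([9], [1]) == pytest.approx(0.9)

    def test_no_false_positives(self):
        assert precision([4, 6], [0, 0]) == 1.0

    def test_summed_over_samples(self):
        assert precision([3, 2], [1, 4]) == pytest.approx(0.5)

    def test_all_zero_flagged(self):
        with pytest.raises(ValueError, match="undefined"):
            precision([0], [0])

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            precision([-1], [2])


class TestRmse:
    def test_identical_zero(self):
        assert rmse([1, 2, 3], [1, 2, 3]) == 0.0

    def test_single_pair(self):
        assert rmse([0.0], [3.0]) == 3.0

    def test_closed_form(self):
        assert rmse([0, 0], [3, 4]) == pytest.approx(math.sqrt(12.5))

    def test_2d_uses_euclidean_residual(self):
        assert rmse([[0, 0]], [[3, 4]]) == pytest.approx(5.0)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            rmse([1, 2], [1])

    @given(st.lists(st.tuples(finite, finite), min_size=1, max_size=20))
    @settings(max_examples=50, deadline=None)
    def test_norm_inequality(self, pairs):
        a = [p[0] for p in pairs]
        b = [p[1] for p in pairs]
        n = len(pairs)
        max_resid = max(abs(x - y) for x, y in pairs)
        assert rmse(a, b) >= max_resid / math.sqrt(n) - 1e-9


class TestAngularError:
    def test_equal_vectors_zero(self):
        assert angular_error([1, 2, 3], [1, 2, 3]) == pytest.approx(0.0, abs=1e-5)

    def test_orthogonal_ninety(self):
        assert angular_error([1, 0, 0], [0, 1, 0]) == pytest.approx(90.0)

    def test_forty_five(self):
        assert angular_error([1, 0, 0], [1, 1, 0]) == pytest.approx(45.0)

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            angular_error([0, 0, 0], [1, 0, 0])

    @given(nonzero_vec, nonzero_vec)
    @settings(max_examples=60, deadline=None)
    def test_symmetric(self, a, b):
        assert angular_error(a, b) == pytest.approx(angular_error(b, a), abs=1e-8)

    @given(nonzero_vec, nonzero_vec, st.floats(min_value=1e-2, max_value=1e2))
    @settings(max_examples=60, deadline=None)
    def test_scale_invariant(self, a, b, s):
        scaled = tuple(s * x for x in a)
        assert angular_error(scaled, b) == pytest.approx(angular_error(a, b), abs=1e-5)


class TestGazeAngles:
    def test_screen_center_is_normal(self):
        v = gaze_angles_from_screen((0.0, 0.0), px_per_mm=3.0, viewing_distance_mm=1000.0)
        np.testing.assert_allclose(v, [0, 0, 1], atol=1e-12)

    def test_offset_equal_to_distance_is_45_degrees(self):
        v = gaze_angles_from_screen((3000.0, 0.0), px_per_mm=3.0,
                                    viewing_distance_mm=1000.0)
        assert angular_error(v, [0, 0, 1]) == pytest.approx(45.0)

    def test_small_offset_is_about_one_degree(self):
        # 17.45 mm at 1000 mm -> arctan(0.01745) ~ 1.0 degree
        v = gaze_angles_from_screen((17.45, 0.0), px_per_mm=1.0,
                                    viewing_distance_mm=1000.0)
        assert angular_error(v, [0, 0, 1]) == pytest.approx(1.0, abs=0.01)

    def test_nonpositive_distance_rejected(self):
        with pytest.raises(ValueError):
            gaze_angles_from_screen((0, 0), px_per_mm=3.0, viewing_distance_mm=0.0)


class TestLocalizationError:
    def test_zero(self):
        assert localization_error((0, 0), (0, 0)) == 0.0

    def test_three_four_five(self):
        assert localization_error((0, 0), (3, 4)) == 5.0

    def test_shifted(self):
        assert localization_error((1, 1), (4, 5)) == 5.0


class TestCrossValidate:
    def test_noiseless_second_order_near_exact(self):
        model = synthdata.default_true_model(seed=2)
        sess = synthdata.generate_gaze_session(model, 40, 0.0, seed=1)
        result = cross_validate(sess, k_folds=5, order=2, seed=0)
        assert result.mean_rmse < 1e-6

    def test_leave_one_out_on_12_points(self):
        sess = synthdata.generate_gaze_session(IDENTITY, 12, 0.0, seed=4)
        result = cross_validate(sess, k_folds=12, order=2, seed=0)
        assert len(result.fold_rmse) == 12

    def test_noisy_session_rmse_band(self):
        # per-component noise sd 2 px and Euclidean 2-D residuals give an
        # expected RMSE of 2*sqrt(2) ~ 2.83; band is +/-15% around that
        sess = synthdata.generate_gaze_session(IDENTITY, 500, 2.0, seed=5)
        result = cross_validate(sess, k_folds=5, order=2, seed=0)
        expected = 2.0 * math.sqrt(2.0)
        assert abs(result.mean_rmse - expected) / expected < 0.15

    def test_bad_fold_counts_rejected(self):
        sess = synthdata.generate_gaze_session(IDENTITY, 12, 0.0, seed=4)
        with pytest.raises(ValueError):
            cross_validate(sess, k_folds=1)
        with pytest.raises(ValueError):
            cross_validate(sess, k_folds=13)

    def test_order_comparison_matches_generator(self):
        model = synthdata.default_true_model(seed=3)
        sess = synthdata.generate_gaze_session(model, 60, 0.0, seed=6)
        r2 = cross_validate(sess, k_folds=5, order=2, seed=0)
        r1 = cross_validate(sess, k_folds=5, order=1, seed=0)
        assert r2.mean_rmse < r1.mean_rmse
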