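import numpy as np
import pytest

from vertemorph import (
    CenterPoint,
    FitError,
    ValidationError,
    crop_vertebra,
    default_residual_threshold,
    enumerate_spinal_curve,
    filter_centers,
    fit_spinal_curve,
)


def centers_on(coeffs, ys):
    xs = np.polynomial.polynomial.polyval(np.asarray(ys, float), coeffs)
    return [CenterPoint(float(x), float(y)) for x, y in zip(xs, ys)]


class TestRansacFit:
    def test_quadratic_with_gross_outlier(self):
        """Ten exact quadratic centers plus one displaced 50 px: the outlier
        is flagged and the refit reproduces the generating coefficients."""
        pts = centers_on([2.0, 0.0, 0.01], np.linspace(0, 90, 10))
        pts.append(CenterPoint(pts[5].x + 50.0, pts[5].y + 1.0))
        curve = fit_spinal_curve(pts, residual_threshold=2.0, seed=0)
        assert list(curve.inlier_flags) == [True] * 10 + [False]
        assert curve.degree == 2
        assert np.allclose(curve.coeffs, [2.0, 0.0, 0.01], atol=1e-6)

    def test_collinear_points_fit_line_exactly(self):
        pts = centers_on([5.0, 0.5], [0.0, 10.0, 20.0])
        curve = fit_spinal_curve(pts, residual_threshold=1.0, seed=1)
        assert curve.degree == 1
        assert curve.inlier_flags.all()
        assert np.allclose(curve.residuals(pts), 0.0, atol=1e-9)

    def test_degree_capped_by_point_count(self):
        pts = centers_on([0.0, 1.0], [0.0, 5.0, 11.0, 17.0])
        curve = fit_spinal_curve(pts, max_degree=4, residual_threshold=1.0, seed=2)
        assert curve.degree <= 3  # n - 1 with four centers

    def test_lower_degree_wins_ties(self):
        # exactly linear data: every degree fits all points; degree 1 chosen
        pts = centers_on([1.0, 2.0], np.linspace(0, 50, 8))
        curve = fit_spinal_curve(pts, residual_threshold=1.0, seed=3)
        assert curve.degree == 1

    def test_deterministic_for_fixed_seed(self):
        rng = np.random.default_rng(4)
        pts = [CenterPoint(float(x), float(y))
               for x, y in zip(rng.uniform(0, 50, 9), np.linspace(0, 80, 9))]
        a = fit_spinal_curve(pts, residual_threshold=5.0, seed=42)
        b = fit_spinal_curve(pts, residual_threshold=5.0, seed=42)
        assert np.array_equal(a.inlier_flags, b.inlier_flags)
        assert np.array_equal(a.coeffs, b.coeffs)

    def test_fewer_than_two_centers_rejected(self):
        with pytest.raises(ValidationError):
            fit_spinal_curve([CenterPoint(0, 0)])

    def test_all_degenerate_samples_raise_fit_error(self):
        pts = [CenterPoint(0.0, 5.0), CenterPoint(10.0, 5.0), CenterPoint(3.0, 5.0)]
        with pytest.raises(FitError):
            fit_spinal_curve(pts, residual_threshold=1.0, seed=0)

    def test_refit_residuals_never_exceed_threshold(self):
        rng = np.random.default_rng(8)
        for trial in range(10):
            ys = np.sort(rng.uniform(0, 100, 8))
            xs = 100 + 0.3 * ys + rng.normal(0, 1.0, 8)
            pts = [CenterPoint(float(x), float(y)) for x, y in zip(xs, ys)]
            curve = fit_spinal_curve(pts, residual_threshold=3.0, seed=trial)
            resid = curve.residuals(pts)
            assert (resid[curve.inlier_flags] <= 3.0 + 1e-12).all()

    def test_monotone_robustness_to_added_outlier(self):
        """Adding one gross outlier never changes the retained true centers."""
        pts = centers_on([10.0, 0.2, 0.002], np.linspace(0, 90, 9))
        before = fit_spinal_curve(pts, residual_threshold=2.0, seed=0)
        assert before.inlier_flags.all()
        with_outlier = pts + [CenterPoint(pts[4].x + 80.0, pts[4].y + 2.0)]
        after = fit_spinal_curve(with_outlier, residual_threshold=2.0, seed=0)
        assert list(after.inlier_flags[:9]) == [True] * 9
        assert not after.inlier_flags[9]


class TestEnumerationOracle:
    def test_matches_ransac_on_small_sets(self):
        """For <= 8 centers and degree <= 2, randomized RANSAC finds the same
        inlier set as exhaustive enumeration of all minimal samples."""
        rng = np.random.default_rng(0)
        for trial in range(20):
            n = int(rng.integers(5, 9))
            ys = np.sort(rng.uniform(0, 100, n))
            coeffs = rng.uniform(-1, 1, 3) * [50, 0.5, 0.005]
            xs = np.polynomial.polynomial.polyval(ys, coeffs)
            xs[int(rng.integers(0, n))] += 60 * rng.choice([-1.0, 1.0])
            pts = [CenterPoint(float(x), float(y)) for x, y in zip(xs, ys)]
            r = fit_spinal_curve(pts, max_degree=2, residual_threshold=2.0, seed=trial)
            e = enumerate_spinal_curve(pts, max_degree=2, residual_threshold=2.0)
            assert np.array_equal(r.inlier_flags, e.inlier_flags)


class TestFilterCenters:
    def test_all_inliers_returned_unchanged(self):
        pts = centers_on([0.0, 1.0], [0.0, 10.0, 20.0])
        curve = fit_spinal_curve(pts, residual_threshold=1.0, seed=0)
        assert filter_centers(pts, curve) == pts

    def test_all_outliers_yield_empty_list(self):
        pts = centers_on([0.0, 1.0], [0.0, 10.0, 20.0])
        curve = fit_spinal_curve(pts, residual_threshold=1.0, seed=0)
        object.__setattr__(curve, "inlier_flags", np.zeros(3, dtype=bool))
        assert filter_centers(pts, curve) == []

    def test_length_mismatch_rejected(self):
        pts = centers_on([0.0, 1.0], [0.0, 10.0, 20.0])
        curve = fit_spinal_curve(pts, residual_threshold=1.0, seed=0)
        with pytest.raises(ValidationError):
            filter_centers(pts[:2], curve)


class TestDefaultThreshold:
    def test_half_median_nearest_neighbor_spacing(self):
        pts = [CenterPoint(0, 0), CenterPoint(0, 10), CenterPoint(0, 20),
               CenterPoint(0, 34)]
        # NN distances: 10, 10, 10, 14 -> median 10 -> threshold 5
        assert default_residual_threshold(pts) == pytest.approx(5.0)


class TestCrop:
    def test_center_of_matching_image_is_identity_window(self):
        img = np.arange(224 * 224, dtype=float).reshape(224, 224)
        crop, window = crop_vertebra(img, CenterPoint(112, 112), side=224)
        assert np.array_equal(crop, img)
        assert window.padding == (0, 0, 0, 0)

    def test_corner_center_pads_top_left(self):
        img = np.ones((300, 300))
        crop, window = crop_vertebra(img, CenterPoint(10, 10), side=224, fill=0.0)
        assert crop.shape == (224, 224)
        top, bottom, left, right = window.padding
        assert (top, left) == (102, 102) and (bottom, right) == (0, 0)
        assert crop[0, 0] == 0.0 and crop[223, 223] == 1.0

    def test_round_trip_is_exact(self):
        img = np.zeros((500, 400))
        _, window = crop_vertebra(img, CenterPoint(300.3, 400.2), side=224)
        pt = np.array([[17.25, 203.5]])
        back = window.image_to_crop(window.crop_to_image(pt))
        assert np.allclose(back, pt, atol=1e-9)
        # the rounded image center maps to the crop center pixel
        cc = window.image_to_crop(np.array([[300.0, 400.0]]))
        assert np.allclose(cc, [[112.0, 112.0]])

    def test_center_outside_image_rejected(self):
        with pytest.raises(ValidationError):
            crop_vertebra(np.zeros((100, 100)), CenterPoint(150, 50))
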