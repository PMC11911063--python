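import itertools
import math

import numpy as np
import pytest

from vertemorph import (
    CenterPoint,
    DetectionCounts,
    LandmarkSet,
    OracleLandmarkBackend,
    ValidationError,
    bland_altman,
    correlation,
    detection_metrics,
    evaluate_pipeline,
    landmark_errors,
    match_detections,
    run_pipeline,
    vertebra_dimensions,
)

from conftest import rectangle_landmarks, truth_records

WEDGE = LandmarkSet(
    AU=(0, 4), AL=(0, 10), CU=(5, 2), CL=(5, 10), PU=(10, 0), PL=(10, 10),
    frame="image",
)


class TestMatching:
    def test_exact_hit_is_tp(self):
        flags, counts = match_detections(
            [CenterPoint(5, 5)], [CenterPoint(5, 5)], tau=1.0
        )
        assert flags == [True] and counts.TP == 1 and counts.FP == 0

    def test_nearer_of_two_predictions_wins(self):
        flags, counts = match_detections(
            [CenterPoint(5, 6), CenterPoint(5, 5.5)], [CenterPoint(5, 5)], tau=3.0
        )
        assert flags == [False, True]
        assert counts.TP == 1 and counts.FP == 1

    def test_beyond_tau_is_fp(self):
        flags, counts = match_detections(
            [CenterPoint(0, 0)], [CenterPoint(10, 0)], tau=5.0
        )
        assert flags == [False] and counts.FP == 1

    def test_empty_reference_all_fp(self):
        flags, counts = match_detections(
            [CenterPoint(0, 0), CenterPoint(1, 1)], [], tau=5.0
        )
        assert flags == [False, False]
        assert counts == DetectionCounts(0, 0, 2, 1)

    def test_greedy_equals_optimal_assignment_on_small_cases(self):
        """For <= 6 predictions/references the greedy TP count equals the
        best one-to-one assignment's whenever matched distances fit tau."""
        rng = np.random.default_rng(3)
        for _ in range(30):
            n_p, n_r = int(rng.integers(1, 7)), int(rng.integers(1, 7))
            preds = [CenterPoint(*xy) for xy in rng.uniform(0, 30, (n_p, 2))]
            refs = [CenterPoint(*xy) for xy in rng.uniform(0, 30, (n_r, 2))]
            tau = 8.0
            _, counts = match_detections(preds, refs, tau)
            best = 0
            for k in range(min(n_p, n_r), -1, -1):
                if best:
                    break
                for ps in itertools.permutations(range(n_p), k):
                    for rs in itertools.combinations(range(n_r), k):
                        if all(
                            math.hypot(preds[p].x - refs[r].x,
                                       preds[p].y - refs[r].y) <= tau
                            for p, r in zip(ps, rs)
                        ):
                            best = max(best, k)
            assert counts.TP == best


class TestDetectionMetrics:
    def test_published_worked_example(self):
        counts = DetectionCounts(n_reference=1582, TP=1544, FP=79, n_images=188)
        m = detection_metrics(counts)
        assert m.sensitivity_pct == 97.6
        assert m.precision_pct == 95.1
        assert m.fp_per_image == pytest.approx(79 / 188)

    def test_exact_rational_arithmetic(self):
        m = detection_metrics(DetectionCounts(8, 6, 2, 4))
        assert m.sensitivity == pytest.approx(0.75)
        assert m.precision == pytest.approx(0.75)
        assert m.fp_per_image == pytest.approx(0.5)

    def test_zero_denominators_yield_markers(self):
        m = detection_metrics(DetectionCounts(0, 0, 0, 1))
        assert m.sensitivity is None and m.precision is None
        assert m.fp_per_image == 0.0

    def test_tp_cannot_exceed_reference(self):
        with pytest.raises(ValidationError):
            DetectionCounts(n_reference=2, TP=3, FP=0)


class TestDimensionsAndErrors:
    def test_rectangle_dimensions(self):
        assert vertebra_dimensions(rectangle_landmarks()) == pytest.approx((10, 10))

    def test_wedge_dimensions(self):
        w, h = vertebra_dimensions(WEDGE)
        assert w == pytest.approx(0.5 * (math.hypot(10, 4) + 10))
        assert h == pytest.approx(8.0)

    def test_dimensions_scale_linearly(self):
        doubled = LandmarkSet.from_array(2 * WEDGE.as_array(), frame="image")
        w, h = vertebra_dimensions(WEDGE)
        assert vertebra_dimensions(doubled) == pytest.approx((2 * w, 2 * h))

    def test_shifted_landmark_error_percent(self):
        ref = rectangle_landmarks()
        moved = ref.as_array()
        moved[0] += [0.5, 0.0]  # AU
        rec = landmark_errors(LandmarkSet.from_array(moved, frame="image"), ref)
        assert rec.x_error_pct["AU"] == pytest.approx(5.0)
        assert rec.y_error_pct["AU"] == 0.0
        assert all(v == 0 for k, v in rec.x_error_pct.items() if k != "AU")

    def test_identical_sets_have_zero_error(self):
        rec = landmark_errors(WEDGE, WEDGE)
        assert rec.mean_error_pct() == 0.0

    def test_y_shift_against_height_eight(self):
        moved = WEDGE.as_array()
        moved[:, 1] += 1.0
        rec = landmark_errors(LandmarkSet.from_array(moved, frame="image"), WEDGE)
        assert all(v == pytest.approx(100 / 8) for v in rec.y_error_pct.values())

    def test_percent_errors_scale_invariant(self):
        ref = WEDGE
        pred = LandmarkSet.from_array(ref.as_array() + 0.7, frame="image")
        r1 = landmark_errors(pred, ref)
        r2 = landmark_errors(
            LandmarkSet.from_array(3 * pred.as_array(), frame="image"),
            LandmarkSet.from_array(3 * ref.as_array(), frame="image"),
        )
        for n in r1.x_error_pct:
            assert r2.x_error_pct[n] == pytest.approx(r1.x_error_pct[n])
            assert r2.y_error_pct[n] == pytest.approx(r1.y_error_pct[n])


class TestCorrelation:
    def test_identity_series_correlate_perfectly(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 1, 30)
        res = correlation(a, a)
        assert res.coefficient == pytest.approx(1.0)

    def test_heavy_tailed_monotone_uses_spearman(self):
        rng = np.random.default_rng(1)
        a = rng.standard_cauchy(50)
        b = np.exp(np.clip(a, -20, 20))  # strictly monotone in a
        res = correlation(a, b)
        assert res.method == "spearman"
        assert res.coefficient == pytest.approx(1.0)

    def test_normal_pairs_use_pearson(self):
        rng = np.random.default_rng(2)
        a = rng.normal(0, 1, 200)
        b = a + rng.normal(0, 1, 200)
        res = correlation(a, b)
        assert res.method == "pearson"

    def test_independent_normals_are_uncorrelated(self):
        rng = np.random.default_rng(3)
        res = correlation(rng.normal(0, 1, 1000), rng.normal(0, 1, 1000))
        assert abs(res.coefficient) < 0.1

    def test_constant_series_marker(self):
        res = correlation(np.ones(10), np.arange(10.0))
        assert res.method is None and math.isnan(res.coefficient)

    def test_small_n_exact_spearman_p(self):
        # n = 8, perfect monotone with one gross outlier to fail normality:
        # exact two-sided permutation p = 2/8!
        a = np.arange(1.0, 9.0)
        b = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 1e6])
        res = correlation(a, b)
        assert res.method == "spearman"
        assert res.coefficient == pytest.approx(1.0)
        assert res.p_value == pytest.approx(2 / math.factorial(8))


class TestBlandAltman:
    def test_identical_series(self):
        a = np.array([1.0, 2.0, 3.0])
        res = bland_altman(a, a)
        assert res.md == 0.0 and res.loa == (0.0, 0.0)
        assert res.within_loa.all()
        assert res.trend_slope is None  # zero-variance differences

    def test_unit_sd_differences(self):
        b = np.zeros(3)
        res = bland_altman(np.array([-1.0, 0.0, 1.0]), b)
        assert res.md == pytest.approx(0.0)
        assert res.sd_diff == pytest.approx(1.0)  # sample SD, ddof = 1
        assert res.loa == pytest.approx((-1.96, 1.96))

    def test_loa_symmetry(self):
        rng = np.random.default_rng(5)
        res = bland_altman(rng.normal(1, 0.2, 100), rng.normal(1, 0.2, 100))
        assert (res.loa[1] - res.md) == pytest.approx(res.md - res.loa[0], abs=1e-12)

    def test_normal_differences_cover_95_percent(self):
        rng = np.random.default_rng(6)
        a = rng.normal(0, 0.1, 10_000)
        res = bland_altman(a, np.zeros_like(a))
        assert res.within_loa_fraction == pytest.approx(0.95, abs=0.01)

    def test_subgroups_use_global_loa(self):
        rng = np.random.default_rng(7)
        a = np.concatenate([rng.normal(0, 0.01, 50), rng.normal(0.3, 0.01, 10)])
        bins = ["<20"] * 50 + [">40"] * 10
        res = bland_altman(a, np.zeros_like(a), qm_bins=bins)
        rows = {r["qm_bin"]: r for r in res.subgroups}
        assert rows["<20"]["n"] == 50 and rows[">40"]["n"] == 10
        # the offset subgroup falls largely outside the single global LOA
        assert rows[">40"]["within_loa_pct"] < rows["<20"]["within_loa_pct"]

    def test_proportional_bias_recovered(self):
        rng = np.random.default_rng(8)
        m = rng.uniform(0, 1, 500)
        d = 0.5 * m + rng.normal(0, 0.01, 500)
        res = bland_altman(m + d / 2, m - d / 2)
        assert res.trend_slope == pytest.approx(0.5, abs=0.02)
        assert res.trend_p < 1e-6 and res.trend_r2 > 0.9

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValidationError):
            bland_altman([1.0], [1.0])


class TestFullReport:
    def test_identity_run(self, mixed_phantom):
        ref = truth_records(mixed_phantom)
        report = evaluate_pipeline(ref, ref)
        m = report["detection"]["metrics"]
        assert m.sensitivity_pct == 100.0 and m.fp_per_image == 0.0
        assert report["landmark_errors"]["overall"]["overall_mean_error_pct"] == 0.0
        for res in report["correlations"].values():
            assert res.coefficient == pytest.approx(1.0)
        assert report["discrepancies"]["n_flagged"] == 0
        assert report["n_paired"] == 14

    def test_missing_prediction_counts_as_non_detection(self, mixed_phantom):
        ref = truth_records(mixed_phantom)
        pred = ref[1:]  # drop the T4 prediction
        report = evaluate_pipeline(pred, ref)
        assert report["n_paired"] == 13
        assert report["n_reference_missing_prediction"] == 1
        assert report["detection"]["counts"].TP == 13
        assert report["detection"]["metrics"].sensitivity == pytest.approx(13 / 14)

    def test_no_overlap_rejected(self, mixed_phantom):
        ref = truth_records(mixed_phantom, image_id="a")
        pred = truth_records(mixed_phantom, image_id="b")
        with pytest.raises(ValidationError):
            evaluate_pipeline(pred, ref)

    def test_noisy_oracle_run_stays_within_loa(self, wedge_phantom):
        """Oracle noise SD 2 px on the standard phantom: the report completes
        and at least 90% of paired ratios sit within the global LOA."""
        backend = OracleLandmarkBackend(
            wedge_phantom.truth_landmarks, noise_sd=2.0, seed=9
        )
        from vertemorph import pipeline_records

        result = run_pipeline(wedge_phantom.image, backend)
        pred = pipeline_records(result, image_id="img-0")
        report = evaluate_pipeline(pred, truth_records(wedge_phantom))
        for res in report["bland_altman"].values():
            assert res.within_loa_fraction >= 0.9
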