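import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _oracles import brute_force_froc, make_match_result, mann_whitney_auc
from petnorm.evaluation import (
    FROCCurve,
    OperatingPoint,
    baseline_abs_error,
    baseline_suv_threshold,
    compare_methods,
    froc_curve,
    roc_from_scores,
    sensitivity_at_fp_rate,
    slice_records,
    slice_roc,
    voxel_roc,
)
from petnorm.io_volumes import Volume
from petnorm.phantom import LesionAnnotation, LesionInfo


_mann_whitney_auc = mann_whitney_auc
_match_result = make_match_result
_brute_force_froc = brute_force_froc


class TestROC:
    def test_perfect_separation(self):
        scores = np.array([10.0] * 5 + [0.0] * 5)
        labels = np.array([True] * 5 + [False] * 5)
        assert roc_from_scores(scores, labels).auroc == pytest.approx(1.0)

    def test_all_ties_gives_half(self):
        scores = np.ones(10)
        labels = np.array([True] * 4 + [False] * 6)
        assert roc_from_scores(scores, labels).auroc == pytest.approx(0.5)

    def test_endpoints_are_corners(self, rng):
        curve = roc_from_scores(rng.standard_normal(30),
                                rng.random(30) > 0.5)
        assert (curve.fpr[0], curve.tpr[0]) == (0.0, 0.0)
        assert (curve.fpr[-1], curve.tpr[-1]) == (1.0, 1.0)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_from_scores(np.ones(5), np.ones(5, dtype=bool))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_auroc_equals_mann_whitney(self, seed):
        r = np.random.default_rng(seed)
        n = int(r.integers(4, 100))
        scores = np.round(r.standard_normal(n), 1)  # rounding forces ties
        labels = r.random(n) > 0.4
        if labels.all() or not labels.any():
            labels[0] = not labels[0]
        auroc = roc_from_scores(scores, labels).auroc
        assert auroc == pytest.approx(_mann_whitney_auc(scores, labels), abs=1e-12)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_invariant_under_monotone_transform(self, seed):
        r = np.random.default_rng(seed)
        scores = r.standard_normal(40)
        labels = r.random(40) > 0.5
        if labels.all() or not labels.any():
            labels[0] = not labels[0]
        a1 = roc_from_scores(scores, labels).auroc
        a2 = roc_from_scores(np.exp(2 * scores), labels).auroc
        assert a1 == pytest.approx(a2, abs=1e-12)


class TestVoxelROC:
    def test_pools_scans_and_uses_masks(self, rng):
        scores = [rng.standard_normal((4, 4, 2)) for _ in range(2)]
        mask = np.zeros((4, 4, 2), dtype=np.uint8)
        mask[1, 1, 0] = 1
        scores[0][1, 1, 0] = 50.0
        curve = voxel_roc(scores, [mask, None])
        assert curve.auroc == pytest.approx(1.0)

    def test_no_positives_rejected(self, rng):
        with pytest.raises(ValueError):
            voxel_roc([rng.standard_normal((3, 3, 3))], [None])


class TestSliceRecords:
    def test_labels_and_maxima(self, rng):
        suv = rng.random((5, 5, 4))
        z = rng.standard_normal((5, 5, 4))
        mask = np.zeros((5, 5, 4), dtype=np.uint8)
        mask[2, 2, 1] = 1  # single annotated voxel -> slice 1 abnormal
        records = slice_records("s", suv, z, mask)
        assert [r.label for r in records] == [False, True, False, False]
        for k, rec in enumerate(records):
            assert rec.score_suv_max == pytest.approx(suv[:, :, k].max())
            assert rec.score_z_max == pytest.approx(z[:, :, k].max())

    def test_all_zero_mask_all_normal(self, rng):
        records = slice_records("s", rng.random((4, 4, 3)),
                                rng.random((4, 4, 3)),
                                np.zeros((4, 4, 3)))
        assert not any(r.label for r in records)

    def test_slice_roc_from_records(self, rng):
        suv = rng.random((4, 4, 6))
        z = rng.standard_normal((4, 4, 6))
        mask = np.zeros((4, 4, 6), dtype=np.uint8)
        mask[0, 0, 2] = 1
        z[:, :, 2] += 100.0
        records = slice_records("s", suv, z, mask)
        assert slice_roc(records, "z").auroc == pytest.approx(1.0)

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            slice_records("s", rng.random((4, 4, 3)), rng.random((4, 4, 2)), None)


class TestFROC:
    def test_spec_toy_example(self):
        # scan1: TP peak 9 (lesion 1), FP peak 5; scan2: TP peak 7 (lesion 1),
        # FP peak 4; 3 lesions total (scan1 has 2, one undetected)
        r1 = _match_result("s1", [(9.0, 1)], [5.0], n_lesions=2)
        r2 = _match_result("s2", [(7.0, 1)], [4.0], n_lesions=1)
        curve = froc_curve([r1, r2])
        got = list(zip(curve.fps_per_scan, curve.sensitivity))
        assert (0.0, 1 / 3) in got
        assert (1.0, 2 / 3) in got
        assert got == sorted(_brute_force_froc([r1, r2]))

    def test_perfect_detection_reaches_one_at_zero_fp(self):
        r = _match_result("s", [(5.0, 1), (4.0, 2)], [], n_lesions=2)
        curve = froc_curve([r])
        assert curve.sensitivity[curve.fps_per_scan == 0].max() == 1.0

    def test_no_candidates_gives_origin(self):
        r = _match_result("s", [], [], n_lesions=2)
        curve = froc_curve([r])
        assert list(curve.fps_per_scan) == [0.0]
        assert list(curve.sensitivity) == [0.0]

    def test_zero_lesions_rejected(self):
        r = _match_result("s", [], [1.0], n_lesions=0)
        with pytest.raises(ValueError):
            froc_curve([r])

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_matches_exhaustive_enumeration(self, seed):
        r = np.random.default_rng(seed)
        results = []
        for s in range(int(r.integers(1, 4))):
            n_lesions = int(r.integers(0, 4))
            tps = [
                (float(np.round(r.uniform(3, 10), 1)), int(lesion))
                for lesion in r.integers(1, n_lesions + 1, size=r.integers(0, 4))
            ] if n_lesions else []
            fps = list(np.round(r.uniform(3, 10, size=r.integers(0, 5)), 1))
            results.append(_match_result(f"s{s}", tps, fps, n_lesions))
        if sum(res.n_lesions for res in results) == 0:
            results.append(_match_result("sx", [(5.0, 1)], [], 1))
        curve = froc_curve(results)
        got = sorted(zip(curve.fps_per_scan, curve.sensitivity))
        expected = sorted(_brute_force_froc(results))
        assert got == pytest.approx(expected)

    def test_sensitivity_at_fp_rate_step_convention(self):
        curve = FROCCurve(np.array([0.5, 2.0]), np.array([0.4, 0.8]), 2, 5)
        assert sensitivity_at_fp_rate(curve, 0.0) == 0.0
        assert sensitivity_at_fp_rate(curve, 1.0) == 0.4
        assert sensitivity_at_fp_rate(curve, 100.0) == 0.8
        with pytest.raises(ValueError):
            sensitivity_at_fp_rate(curve, -1.0)


def _toy_annotation(centroid_vox, spacing=(3.0, 3.0, 3.0)):
    mask = np.zeros((12, 12, 6), dtype=np.uint8)
    mask[centroid_vox] = 1
    centroid = tuple(float(c * s) for c, s in zip(centroid_vox, spacing))
    return LesionAnnotation(
        mask=Volume(mask, spacing),
        lesions=[LesionInfo(1, centroid, 1.0, 1)],
    )


class TestBaselines:
    def test_suv_threshold_detects_isolated_hot_lesion(self):
        suv = np.full((12, 12, 6), 0.5)
        suv[5, 5, 2] = 3.0
        ann = _toy_annotation((5, 5, 2))
        pt = baseline_suv_threshold([suv], [ann], threshold=1.0)
        assert pt.sensitivity == 1.0 and pt.fps_per_scan == 0.0

    def test_threshold_above_max_gives_origin(self):
        suv = np.full((12, 12, 6), 0.5)
        pt = baseline_suv_threshold([suv], [_toy_annotation((5, 5, 2))], 2.0)
        assert (pt.fps_per_scan, pt.sensitivity) == (0.0, 0.0)

    def test_suv_threshold_counts_match_hand_enumeration(self):
        suv = np.full((12, 12, 6), 0.2)
        suv[5, 5, 2] = 3.0  # TP component at the lesion
        suv[0, 0, 0] = 3.0  # far-away FP component
        ann = _toy_annotation((5, 5, 2))
        pt = baseline_suv_threshold([suv], [ann], threshold=1.0)
        assert pt.sensitivity == 1.0 and pt.fps_per_scan == 1.0

    def test_abs_error_perfect_prediction_gives_origin(self):
        actual = np.random.default_rng(0).random((12, 12, 6))
        pt = baseline_abs_error([actual], [actual], [_toy_annotation((5, 5, 2))],
                                threshold=0.5)
        assert (pt.fps_per_scan, pt.sensitivity) == (0.0, 0.0)

    def test_abs_error_detects_superthreshold_residual(self):
        predicted = np.full((12, 12, 6), 1.0)
        actual = predicted.copy()
        actual[5, 5, 2] += 2.0
        pt = baseline_abs_error([predicted], [actual], [_toy_annotation((5, 5, 2))],
                                threshold=1.0)
        assert pt.sensitivity == 1.0 and pt.fps_per_scan == 0.0


class TestCompareMethods:
    def test_single_method_report(self):
        curve = FROCCurve(np.array([0.0, 1.0]), np.array([0.5, 1.0]), 2, 2)
        report = compare_methods(curve, [])
        assert report["baselines"] == []
        assert report["dominates_all_baselines"] is None
        assert report["bayesian"]["sensitivity_at"]["3.0"] == 1.0

    def test_dominance_check(self):
        curve = FROCCurve(np.array([0.0, 2.0]), np.array([0.6, 0.9]), 2, 10)
        good = OperatingPoint(2.0, 0.5, "weak")
        bad = OperatingPoint(0.0, 0.95, "strong")
        report = compare_methods(curve, [good, bad])
        assert report["dominance"]["weak"] is True
        assert report["dominance"]["strong"] is False
        assert report["dominates_all_baselines"] is False
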