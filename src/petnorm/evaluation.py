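"""Three-level detection evaluation: per-voxel ROC, per-slice ROC, per-lesion FROC.

Per-voxel: ROC of a voxel score (Z or raw SUV) discriminating annotated
from non-annotated voxels.  Per-slice: ROC of the slice-maximum score,
where a slice is abnormal iff it contains at least one annotated voxel.
Per-lesion: FROC over candidate regions extracted at a base threshold;
the curve sweeps a decision threshold over candidate peak scores, and
sensitivity is detected lesions / total lesions while the false-positive
rate is unmatched candidates per evaluated scan (normal and abnormal
evaluation scans both count in the denominator).

Two baselines mirror the standard alternatives to a normative Z score:
absolute SUV thresholding, and the absolute prediction error of a
mean-only regressor.  Each yields a single operating point under the
same candidate extraction and centroid matching rules.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Sequence

import numpy as np
from sklearn import metrics as _skmetrics

from .anomaly_map import Candidate, MatchResult, extract_candidates, match_candidates
from .phantom import LesionAnnotation

__all__ = [
    "ROCCurve",
    "SliceRecord",
    "FROCCurve",
    "OperatingPoint",
    "voxel_roc",
    "roc_from_scores",
    "slice_records",
    "slice_roc",
    "froc_curve",
    "sensitivity_at_fp_rate",
    "baseline_suv_threshold",
    "baseline_abs_error",
    "compare_methods",
]


@dataclasses.dataclass
class ROCCurve:
    """Operating points (FPR, TPR) with trapezoidal AUROC."""

    fpr: np.ndarray
    tpr: np.ndarray
    auroc: float

    def __post_init__(self) -> None:
        if np.any(np.diff(self.fpr) < 0) or np.any(np.diff(self.tpr) < 0):
            raise ValueError("ROC points must be non-decreasing")
        area = float(np.trapezoid(self.tpr, self.fpr))
        if abs(area - self.auroc) > 1e-9:
            raise ValueError("stored auroc inconsistent with stored points")


@dataclasses.dataclass
class SliceRecord:
    scan_id: str
    axial_index: int
    label: bool  # abnormal iff the slice contains >= 1 annotated voxel
    score_suv_max: float
    score_z_max: float


@dataclasses.dataclass
class FROCCurve:
    """(FPs per scan, lesion sensitivity) operating points."""

    fps_per_scan: np.ndarray
    sensitivity: np.ndarray
    n_scans: int
    n_lesions: int

    def __post_init__(self) -> None:
        order = np.argsort(self.fps_per_scan, kind="stable")
        self.fps_per_scan = np.asarray(self.fps_per_scan, float)[order]
        self.sensitivity = np.asarray(self.sensitivity, float)[order]
        if np.any(self.sensitivity < 0) or np.any(self.sensitivity > 1):
            raise ValueError("sensitivity must lie in [0, 1]")
        if np.any(np.diff(self.sensitivity) < 0):
            raise ValueError("sensitivity must be non-decreasing with FPs/scan")


@dataclasses.dataclass
class OperatingPoint:
    """A single (FPs/scan, sensitivity) point from a baseline detector."""

    fps_per_scan: float
    sensitivity: float
    method: str = ""
    threshold: float = float("nan")


def roc_from_scores(scores: np.ndarray, labels: np.ndarray) -> ROCCurve:
    """ROC over all distinct score thresholds, ties grouped; AUROC by trapezoid."""
    scores = np.asarray(scores, dtype=np.float64).ravel()
    labels = np.asarray(labels, dtype=bool).ravel()
    if labels.all() or not labels.any():
        raise ValueError("ROC needs at least one positive and one negative")
    fpr, tpr, _ = _skmetrics.roc_curve(labels, scores, drop_intermediate=False)
    return ROCCurve(fpr=fpr, tpr=tpr, auroc=float(np.trapezoid(tpr, fpr)))


def voxel_roc(
    score_volumes: Sequence[np.ndarray],
    annotation_masks: Sequence[np.ndarray | None],
    evaluation_masks: Sequence[np.ndarray | None] | None = None,
) -> ROCCurve:
    """Per-voxel ROC pooled over scans.

    Positives are annotated voxels; negatives are all non-annotated
    voxels, optionally restricted by per-scan evaluation masks.
    """
    all_scores, all_labels = [], []
    for i, scores in enumerate(score_volumes):
        scores = np.asarray(scores)
        ann = annotation_masks[i]
        labels = np.zeros(scores.shape, dtype=bool) if ann is None else (
            np.asarray(ann) > 0)
        if labels.shape != scores.shape:
            raise ValueError("annotation mask shape mismatch")
        keep = np.ones(scores.shape, dtype=bool)
        if evaluation_masks is not None and evaluation_masks[i] is not None:
            keep = np.asarray(evaluation_masks[i]) > 0
            keep = keep | labels  # positives always evaluated
        all_scores.append(scores[keep].ravel())
        all_labels.append(labels[keep].ravel())
    return roc_from_scores(np.concatenate(all_scores), np.concatenate(all_labels))


def slice_records(
    scan_id: str,
    suv_volume: np.ndarray,
    z_volume: np.ndarray,
    annotation_mask: np.ndarray | None,
) -> list[SliceRecord]:
    """Per-axial-slice labels and slice-maximum SUV / Z scores for one scan."""
    suv = np.asarray(suv_volume)
    z = np.asarray(z_volume)
    if suv.shape != z.shape:
        raise ValueError("SUV and Z volumes must share a shape")
    if annotation_mask is not None and np.asarray(annotation_mask).shape != suv.shape:
        raise ValueError("annotation mask shape mismatch")
    records = []
    for k in range(suv.shape[2]):
        abnormal = (
            bool((np.asarray(annotation_mask)[:, :, k] > 0).any())
            if annotation_mask is not None
            else False
        )
        records.append(
            SliceRecord(
                scan_id=scan_id,
                axial_index=k,
                label=abnormal,
                score_suv_max=float(suv[:, :, k].max()),
                score_z_max=float(z[:, :, k].max()),
            )
        )
    return records


def slice_roc(records: Sequence[SliceRecord], score: str = "z") -> ROCCurve:
    """ROC over slice records using the slice-maximum Z or SUV."""
    if score not in ("z", "suv"):
        raise ValueError("score must be 'z' or 'suv'")
    values = np.array(
        [r.score_z_max if score == "z" else r.score_suv_max for r in records]
    )
    labels = np.array([r.label for r in records])
    return roc_from_scores(values, labels)


def froc_curve(results: Sequence[MatchResult]) -> FROCCurve:
    """FROC from per-scan matched candidates.

    Candidates are fixed (extracted at the base threshold upstream); the
    decision threshold tau sweeps over distinct candidate peak scores
    from high to low.  At each tau, a lesion counts as detected iff some
    TP candidate matching it has peak >= tau, and the FP rate is the
    number of FP candidates with peak >= tau divided by the number of
    scans (normal scans included).
    """
    if len(results) == 0:
        raise ValueError("froc_curve needs at least one scan")
    n_scans = len(results)
    n_lesions = sum(r.n_lesions for r in results)
    if n_lesions == 0:
        raise ValueError("froc_curve needs at least one ground-truth lesion")

    tp_peaks, tp_keys, fp_peaks = [], [], []
    for s, r in enumerate(results):
        for peak, is_tp, lesion in zip(
            r.candidate_peaks, r.candidate_is_tp, r.matched_lesion_id
        ):
            if is_tp:
                tp_peaks.append(float(peak))
                tp_keys.append((s, int(lesion)))
            else:
                fp_peaks.append(float(peak))
    all_peaks = np.array(tp_peaks + fp_peaks)
    if len(all_peaks) == 0:
        return FROCCurve(np.array([0.0]), np.array([0.0]), n_scans, n_lesions)

    tp_peaks_arr = np.array(tp_peaks)
    fp_peaks_arr = np.array(fp_peaks)
    # best (highest) peak per distinct lesion: a lesion is detected at tau
    # iff its best matching TP candidate clears tau
    best_by_lesion: dict[tuple[int, int], float] = {}
    for key, peak in zip(tp_keys, tp_peaks_arr):
        best_by_lesion[key] = max(peak, best_by_lesion.get(key, -np.inf))
    lesion_best = np.array(sorted(best_by_lesion.values())) if best_by_lesion else (
        np.array([]))

    taus = np.unique(all_peaks)[::-1]  # descending; ties grouped
    fps, sens = [], []
    for tau in taus:
        fps.append(float((fp_peaks_arr >= tau).sum()) / n_scans)
        sens.append(float((lesion_best >= tau).sum()) / n_lesions)
    return FROCCurve(np.array(fps), np.array(sens), n_scans, n_lesions)


def sensitivity_at_fp_rate(curve: FROCCurve, fp_per_scan: float) -> float:
    """Highest sensitivity among points with FPs/scan <= the query (step rule)."""
    if fp_per_scan < 0:
        raise ValueError("fp_per_scan must be non-negative")
    ok = curve.fps_per_scan <= fp_per_scan
    if not ok.any():
        return 0.0
    return float(curve.sensitivity[ok].max())


def _operating_point(
    results: Sequence[MatchResult], method: str, threshold: float
) -> OperatingPoint:
    n_scans = len(results)
    n_lesions = sum(r.n_lesions for r in results)
    n_detected = sum(r.n_detected for r in results)
    n_fp = sum(r.n_fp for r in results)
    return OperatingPoint(
        fps_per_scan=n_fp / n_scans,
        sensitivity=(n_detected / n_lesions) if n_lesions else 0.0,
        method=method,
        threshold=threshold,
    )


def _match_scans(
    volumes: Sequence[np.ndarray],
    annotations: Sequence[LesionAnnotation | None],
    threshold: float,
    radius_mm: float,
    spacing: tuple[float, float, float],
    connectivity: int,
    scan_ids: Sequence[str] | None,
) -> list[MatchResult]:
    out = []
    for i, vol in enumerate(volumes):
        sid = scan_ids[i] if scan_ids is not None else f"scan_{i}"
        cands = extract_candidates(
            vol, threshold, connectivity=connectivity, spacing=spacing, scan_id=sid
        )
        out.append(match_candidates(cands, annotations[i], radius_mm, scan_id=sid))
    return out


def baseline_suv_threshold(
    function_volumes: Sequence[np.ndarray],
    annotations: Sequence[LesionAnnotation | None],
    threshold: float,
    radius_mm: float = 5.0,
    spacing: tuple[float, float, float] = (3.0, 3.0, 3.0),
    connectivity: int = 26,
    scan_ids: Sequence[str] | None = None,
) -> OperatingPoint:
    """Abnormal = connected components of {SUV > threshold}; one point."""
    results = _match_scans(function_volumes, annotations, threshold, radius_mm,
                           spacing, connectivity, scan_ids)
    return _operating_point(results, f"suv>{threshold:g}", threshold)


def baseline_abs_error(
    predicted_volumes: Sequence[np.ndarray],
    function_volumes: Sequence[np.ndarray],
    annotations: Sequence[LesionAnnotation | None],
    threshold: float,
    radius_mm: float = 5.0,
    spacing: tuple[float, float, float] = (3.0, 3.0, 3.0),
    connectivity: int = 26,
    scan_ids: Sequence[str] | None = None,
) -> OperatingPoint:
    """Abnormal = components of {actual - predicted > threshold}; one point."""
    diffs = [
        np.asarray(f) - np.asarray(p)
        for f, p in zip(function_volumes, predicted_volumes)
    ]
    results = _match_scans(diffs, annotations, threshold, radius_mm,
                           spacing, connectivity, scan_ids)
    return _operating_point(results, f"abs_err>{threshold:g}", threshold)


def compare_methods(
    bayesian_froc: FROCCurve,
    baseline_points: Sequence[OperatingPoint],
    voxel_aurocs: dict[str, float] | None = None,
    slice_aurocs: dict[str, float] | None = None,
    fp_rates: Sequence[float] = (1.0, 3.0, 10.0),
) -> dict:
    """Method-comparison report with the dominance check.

    Dominance: at each baseline's FPs/scan, the Z-score FROC sensitivity
    is at least the baseline's sensitivity.
    """
    report: dict = {
        "bayesian": {
            "froc_fps_per_scan": [float(v) for v in bayesian_froc.fps_per_scan],
            "froc_sensitivity": [float(v) for v in bayesian_froc.sensitivity],
            "n_scans": bayesian_froc.n_scans,
            "n_lesions": bayesian_froc.n_lesions,
            "sensitivity_at": {
                str(r): sensitivity_at_fp_rate(bayesian_froc, r) for r in fp_rates
            },
        },
        "baselines": [],
        "dominance": {},
    }
    if voxel_aurocs:
        report["voxel_auroc"] = {k: float(v) for k, v in voxel_aurocs.items()}
    if slice_aurocs:
        report["slice_auroc"] = {k: float(v) for k, v in slice_aurocs.items()}
    for pt in baseline_points:
        bayes_sens = sensitivity_at_fp_rate(bayesian_froc, pt.fps_per_scan)
        report["baselines"].append(
            {
                "method": pt.method,
                "threshold": float(pt.threshold),
                "fps_per_scan": float(pt.fps_per_scan),
                "sensitivity": float(pt.sensitivity),
                "bayesian_sensitivity_at_same_fps": bayes_sens,
            }
        )
        report["dominance"][pt.method] = bool(bayes_sens >= pt.sensitivity)
    report["dominates_all_baselines"] = (
        all(report["dominance"].values()) if report["dominance"] else None
    )
    return report
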