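"""Z-score anomaly maps, candidate extraction, and centroid matching.

The anomaly surface is the per-pixel Z score

    Z_i = (y_i - E(y_i)) / sqrt(Var(y_i)),

with the observed functional value ``y_i`` and the normative model's
predicted mean and variance; the variance is floored to keep Z finite.
Lesion candidates are connected components of the superthreshold set
``Z > threshold`` (3-D, 26-connectivity by default, since false
positives are counted per scan and matching uses 3-D mm distances), and
a candidate counts as a true positive iff its unweighted centroid lies
within a fixed physical radius of a true lesion centroid.  Detection is
one-sided: only abnormally *high* uptake is flagged.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage

from .bnn_model import PredictiveMap
from .phantom import LesionAnnotation

__all__ = [
    "ZScoreMap",
    "Candidate",
    "MatchResult",
    "z_score_map",
    "extract_candidates",
    "candidate_centroid",
    "match_candidates",
]


@dataclasses.dataclass
class ZScoreMap:
    """Per-pixel Z scores (dimensionless), per slice or stacked per volume."""

    z: np.ndarray

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.z)):
            raise ValueError("Z map contains non-finite values")


@dataclasses.dataclass(eq=False)
class Candidate:
    """A connected superthreshold region proposed as a lesion."""

    voxels: np.ndarray  # (n, 3) integer indices
    peak_score: float
    centroid_mm: tuple[float, float, float]
    scan_id: str = ""

    def __post_init__(self) -> None:
        if len(self.voxels) == 0:
            raise ValueError("candidate voxel set must be nonempty")


@dataclasses.dataclass
class MatchResult:
    """Candidate/lesion matching for one scan."""

    scan_id: str
    candidate_peaks: np.ndarray  # peak score per candidate
    candidate_is_tp: np.ndarray  # bool per candidate
    matched_lesion_id: np.ndarray  # lesion id per candidate, 0 for FP
    lesion_ids: np.ndarray  # all ground-truth lesion ids of the scan
    lesion_detected: np.ndarray  # bool per lesion (>=1 TP candidate)

    @property
    def n_tp(self) -> int:
        return int(self.candidate_is_tp.sum())

    @property
    def n_fp(self) -> int:
        return int((~self.candidate_is_tp).sum())

    @property
    def n_detected(self) -> int:
        return int(self.lesion_detected.sum())

    @property
    def n_lesions(self) -> int:
        return int(len(self.lesion_ids))


def z_score_map(
    function_values: np.ndarray,
    pred: PredictiveMap,
    variance_floor: float = 1e-6,
) -> ZScoreMap:
    """Elementwise Z_i = (y_i - E(y_i)) / sqrt(max(Var(y_i), floor))."""
    y = np.asarray(function_values, dtype=np.float64)
    if y.shape != pred.mean.shape:
        raise ValueError(f"shape mismatch: y {y.shape} vs mean {pred.mean.shape}")
    denom = np.sqrt(np.maximum(pred.variance, variance_floor))
    return ZScoreMap(z=(y - pred.mean) / denom)


_STRUCTURES = {
    6: ndimage.generate_binary_structure(3, 1),
    26: ndimage.generate_binary_structure(3, 3),
}


def extract_candidates(
    score_volume: np.ndarray,
    threshold: float,
    connectivity: int = 26,
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0),
    scan_id: str = "",
) -> list[Candidate]:
    """Connected components of ``score > threshold`` as candidates.

    Candidates are ordered by descending peak score (ties broken by
    component label) for determinism.
    """
    scores = np.asarray(score_volume)
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    if connectivity not in _STRUCTURES:
        raise ValueError(f"connectivity must be 6 or 26, got {connectivity}")
    mask = scores > threshold
    labels, n = ndimage.label(mask, structure=_STRUCTURES[connectivity])
    candidates = []
    for comp in range(1, n + 1):
        voxels = np.argwhere(labels == comp)
        peak = float(scores[labels == comp].max())
        centroid = candidate_centroid(voxels, spacing, origin)
        candidates.append(
            Candidate(voxels=voxels, peak_score=peak, centroid_mm=centroid,
                      scan_id=scan_id)
        )
    candidates.sort(key=lambda c: -c.peak_score)
    return candidates


def candidate_centroid(
    voxels: np.ndarray,
    spacing: tuple[float, float, float],
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0),
) -> tuple[float, float, float]:
    """Unweighted mean of member voxel physical centers, in mm."""
    voxels = np.asarray(voxels)
    if voxels.size == 0:
        raise ValueError("empty voxel set has no centroid")
    mm = np.asarray(origin) + voxels.mean(axis=0) * np.asarray(spacing)
    return tuple(float(c) for c in mm)


def match_candidates(
    candidates: list[Candidate],
    lesions: LesionAnnotation | None,
    radius_mm: float = 5.0,
    scan_id: str = "",
) -> MatchResult:
    """Centroid matching: TP iff within ``radius_mm`` of a lesion centroid.

    Each candidate is matched to its nearest lesion only (ties broken by
    the smaller lesion id); a lesion is detected iff at least one TP
    candidate matches it.  ``lesions=None`` denotes a normal scan (all
    candidates are false positives).
    """
    if radius_mm < 0:
        raise ValueError("radius_mm must be non-negative")
    lesion_list = lesions.lesions if lesions is not None else []
    lesion_ids = np.array([les.lesion_id for les in lesion_list], dtype=int)
    centroids = np.array([les.centroid_mm for les in lesion_list], dtype=float)

    peaks = np.array([c.peak_score for c in candidates], dtype=float)
    is_tp = np.zeros(len(candidates), dtype=bool)
    matched = np.zeros(len(candidates), dtype=int)
    detected = np.zeros(len(lesion_list), dtype=bool)

    for i, cand in enumerate(candidates):
        if len(lesion_list) == 0:
            continue
        d = np.linalg.norm(centroids - np.asarray(cand.centroid_mm), axis=1)
        j = int(np.argmin(d))  # argmin returns the first (smallest id) on ties
        if d[j] <= radius_mm:
            is_tp[i] = True
            matched[i] = lesion_ids[j]
            detected[j] = True
    return MatchResult(
        scan_id=scan_id or (candidates[0].scan_id if candidates else ""),
        candidate_peaks=peaks,
        candidate_is_tp=is_tp,
        matched_lesion_id=matched,
        lesion_ids=lesion_ids,
        lesion_detected=detected,
    )
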