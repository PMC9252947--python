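"""Independent brute-force oracles and small builders shared across tests.

Each oracle re-derives a quantity from first principles (pairwise
comparisons, BFS flood fill, exhaustive threshold enumeration) without
touching the implementation paths it checks.
"""

import numpy as np

from petnorm.anomaly_map import Candidate, MatchResult
from petnorm.io_volumes import Volume
from petnorm.phantom import LesionAnnotation, LesionInfo


def mann_whitney_auc(scores, labels):
    """Pairwise oracle: (wins + ties/2) / (n_pos * n_neg)."""
    pos = scores[labels]
    neg = scores[~labels]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def flood_fill_components(mask, connectivity):
    """BFS flood fill over a boolean 3-D field; returns a set of frozensets."""
    offsets = []
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                if (dx, dy, dz) == (0, 0, 0):
                    continue
                if connectivity == 6 and abs(dx) + abs(dy) + abs(dz) != 1:
                    continue
                offsets.append((dx, dy, dz))
    seen = np.zeros_like(mask, dtype=bool)
    components = []
    for start in np.argwhere(mask):
        start = tuple(start)
        if seen[start]:
            continue
        comp = []
        stack = [start]
        seen[start] = True
        while stack:
            p = stack.pop()
            comp.append(p)
            for off in offsets:
                q = tuple(np.add(p, off))
                if any(c < 0 or c >= s for c, s in zip(q, mask.shape)):
                    continue
                if mask[q] and not seen[q]:
                    seen[q] = True
                    stack.append(q)
        components.append(frozenset(comp))
    return set(components)


def make_match_result(scan_id, tp_peaks_lesions, fp_peaks, n_lesions):
    """Build a MatchResult from (peak, lesion_id) TPs and FP peaks."""
    peaks = np.array([p for p, _ in tp_peaks_lesions] + list(fp_peaks), dtype=float)
    is_tp = np.array([True] * len(tp_peaks_lesions) + [False] * len(fp_peaks),
                     dtype=bool)
    matched = np.array([l for _, l in tp_peaks_lesions] + [0] * len(fp_peaks),
                       dtype=int)
    lesion_ids = np.arange(1, n_lesions + 1)
    detected = np.isin(lesion_ids, matched)
    return MatchResult(scan_id, peaks, is_tp, matched, lesion_ids, detected)


def brute_force_froc(results):
    """Exhaustive enumeration over every candidate peak as threshold."""
    n_scans = len(results)
    n_lesions = sum(r.n_lesions for r in results)
    peaks = sorted({p for r in results for p in r.candidate_peaks}, reverse=True)
    points = []
    for tau in peaks:
        fp = sum(
            ((r.candidate_peaks >= tau) & ~r.candidate_is_tp).sum() for r in results
        )
        detected = 0
        for r in results:
            for lesion in r.lesion_ids:
                hits = (r.candidate_peaks >= tau) & (r.matched_lesion_id == lesion)
                detected += bool(hits.any())
        points.append((fp / n_scans, detected / n_lesions))
    return points


def point_candidate(centroid, peak=5.0):
    return Candidate(voxels=np.array([[0, 0, 0]]), peak_score=peak,
                     centroid_mm=centroid)


def point_annotation(centroids):
    """Single-voxel lesions at the given mm positions (1 mm spacing)."""
    mask = np.zeros((40, 40, 40), dtype=np.uint8)
    lesions = []
    for i, c in enumerate(centroids, start=1):
        vox = tuple(int(round(x)) for x in c)
        mask[vox] = i
        lesions.append(LesionInfo(i, tuple(float(x) for x in c), 1.0, 1))
    return LesionAnnotation(mask=Volume(mask, (1, 1, 1)), lesions=lesions)
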