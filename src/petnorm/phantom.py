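"""Synthetic paired anatomy/function phantoms with known uptake statistics.

The generator emulates the structure a normative uptake model has to
learn from chest PET/CT: region-structured anatomy that predicts tracer
uptake, per-region heteroscedastic SUV variability, and injectable focal
high-uptake lesions with known masks and centroids.

Each axial slice contains an elliptical "body" (soft tissue, label 1)
holding two "lung" ellipses (label 2, low uptake and low variance) and a
central "mediastinum/heart" disc (label 3, high uptake and high
variance), in an "air" background (label 0).  Ellipse parameters are
jittered per scan so anatomy varies across the cohort.

Functional values decompose per region ``r`` into a population mean
``mu_r``, a between-scan offset ``b_r ~ N(0, sigma_b_r^2)`` drawn once
per scan and shared by all voxels of the region (inter-subject
physiologic variation), and within-scan voxel noise
``e ~ N(0, sigma_w_r^2)``.  The marginal per-voxel SD is therefore
``sigma_r = sqrt(sigma_b_r^2 + sigma_w_r^2)``, which is what an ideal
normative model should predict.  SUVs are clipped at 0.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from collections.abc import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .io_volumes import Volume, VolumePair, write_volume

__all__ = [
    "RegionParams",
    "GroundTruthStats",
    "LesionSpec",
    "LesionInfo",
    "LesionAnnotation",
    "PlacementError",
    "DEFAULT_REGIONS",
    "make_phantom_labels",
    "synthesize_pair",
    "inject_lesions",
    "generate_dataset",
]

AIR, SOFT_TISSUE, LUNG, HEART = 0, 1, 2, 3


@dataclasses.dataclass(frozen=True)
class RegionParams:
    """Anatomy value and normal-population uptake statistics of a region."""

    label: int
    name: str
    anatomy_value: float  # HU-like
    uptake_mean: float  # SUV, mu_r
    between_scan_sd: float  # SUV, sigma_b_r
    within_scan_sd: float  # SUV, sigma_w_r

    def __post_init__(self) -> None:
        if self.between_scan_sd < 0 or self.within_scan_sd < 0:
            raise ValueError("region SDs must be non-negative")

    @property
    def total_sd(self) -> float:
        """Marginal per-voxel SD: sqrt(sigma_b^2 + sigma_w^2)."""
        return float(np.hypot(self.between_scan_sd, self.within_scan_sd))


# Default chest-like parameter set.  Uptake ordering heart >> soft tissue
# > lung > air mirrors physiologic FDG uptake; the heart/lung total-SD
# ratio (~9.5x) makes the heteroscedasticity the variance head must
# recover unambiguous.  Air mean is kept above 4 sigma of its noise so
# that clipping SUV at zero leaves the Gaussian statistics intact.
DEFAULT_REGIONS: tuple[RegionParams, ...] = (
    RegionParams(AIR, "air", -1000.0, 0.10, 0.01, 0.02),
    RegionParams(SOFT_TISSUE, "soft_tissue", 40.0, 0.80, 0.10, 0.15),
    RegionParams(LUNG, "lung", -700.0, 0.40, 0.05, 0.08),
    RegionParams(HEART, "heart", 70.0, 2.50, 0.80, 0.40),
)


@dataclasses.dataclass
class GroundTruthStats:
    """True per-voxel population mean and SD (piecewise-constant over regions)."""

    mean_volume: np.ndarray
    sd_volume: np.ndarray

    def __post_init__(self) -> None:
        if self.mean_volume.shape != self.sd_volume.shape:
            raise ValueError("mean and sd volumes must share a shape")
        if np.any(self.sd_volume < 0):
            raise ValueError("sd_volume must be non-negative")


@dataclasses.dataclass(frozen=True)
class LesionSpec:
    """A family of focal uptake lesions to inject.

    ``amplitude_sd`` scales the lesion peak in multiples of the local
    region SD, so lesion conspicuity is defined relative to the local
    normal variability (the quantity a Z-score detector responds to).
    """

    region_label: int
    radius_mm: float  # half-width-at-half-maximum of the Gaussian bump
    amplitude_sd: float
    count: int = 1

    def __post_init__(self) -> None:
        if self.radius_mm <= 0:
            raise ValueError("radius_mm must be positive")
        if self.amplitude_sd <= 0:
            raise ValueError("amplitude_sd must be positive")
        if self.count < 1:
            raise ValueError("count must be >= 1")


@dataclasses.dataclass(frozen=True)
class LesionInfo:
    lesion_id: int
    centroid_mm: tuple[float, float, float]
    peak_added_suv: float
    region_label: int


@dataclasses.dataclass
class LesionAnnotation:
    """Voxel-wise lesion mask (value k for lesion id k) plus per-lesion records."""

    mask: Volume
    lesions: list[LesionInfo]

    def __post_init__(self) -> None:
        ids_in_mask = set(np.unique(self.mask.data)) - {0}
        ids_listed = {les.lesion_id for les in self.lesions}
        if ids_in_mask != ids_listed:
            raise ValueError(
                f"lesion ids in mask {sorted(ids_in_mask)} != listed {sorted(ids_listed)}"
            )


class PlacementError(RuntimeError):
    """No admissible lesion position found after bounded retries."""


def _ellipse_mask(xx: np.ndarray, yy: np.ndarray, center, axes) -> np.ndarray:
    return ((xx - center[0]) / axes[0]) ** 2 + ((yy - center[1]) / axes[1]) ** 2 <= 1.0


def make_phantom_labels(
    shape: tuple[int, int, int],
    seed: int | np.random.Generator,
    spacing: tuple[float, float, float] = (3.0, 3.0, 3.0),
    jitter: float = 0.05,
) -> Volume:
    """Build a deterministic per-scan anatomy label volume.

    Ellipse centers/axes (in units of the in-plane extent) receive a mild
    random jitter per scan; the layout is constant along the axial axis.
    """
    nx, ny, nz = shape
    if nx < 32 or ny < 32:
        raise ValueError(f"in-plane extents must be >= 32, got {(nx, ny)}")
    if nz < 1:
        raise ValueError("axial extent must be >= 1")
    rng = np.random.default_rng(seed)

    def j(lo_hi: float) -> float:
        return float(rng.uniform(-lo_hi, lo_hi))

    def ja() -> float:
        return float(1.0 + rng.uniform(-jitter, jitter))

    body_c = (0.50 + j(0.02), 0.53 + j(0.02))
    body_a = (0.42 * ja(), 0.36 * ja())
    lung_l_c = (0.32 + j(0.015), 0.45 + j(0.015))
    lung_r_c = (0.68 + j(0.015), 0.45 + j(0.015))
    lung_a = (0.13 * ja(), 0.20 * ja())
    heart_c = (0.52 + j(0.015), 0.60 + j(0.015))
    heart_r = 0.11 * ja()

    x = (np.arange(nx) + 0.5) / nx
    y = (np.arange(ny) + 0.5) / ny
    xx, yy = np.meshgrid(x, y, indexing="ij")

    plane = np.zeros((nx, ny), dtype=np.uint8)
    plane[_ellipse_mask(xx, yy, body_c, body_a)] = SOFT_TISSUE
    body = plane > 0
    plane[_ellipse_mask(xx, yy, lung_l_c, lung_a) & body] = LUNG
    plane[_ellipse_mask(xx, yy, lung_r_c, lung_a) & body] = LUNG
    plane[_ellipse_mask(xx, yy, heart_c, (heart_r, heart_r)) & body] = HEART

    labels = np.repeat(plane[:, :, None], nz, axis=2)
    return Volume(labels, spacing)


def _param_lookup(
    params: Sequence[RegionParams], labels: np.ndarray
) -> dict[str, np.ndarray]:
    by_label = {p.label: p for p in params}
    if len(by_label) != len(params):
        raise ValueError("region labels must be unique")
    present = np.unique(labels)
    missing = [int(l) for l in present if int(l) not in by_label]
    if missing:
        raise ValueError(f"no RegionParams for labels {missing}")
    n = max(by_label) + 1
    tables = {
        "anatomy": np.zeros(n),
        "mu": np.zeros(n),
        "sb": np.zeros(n),
        "sw": np.zeros(n),
    }
    for p in by_label.values():
        tables["anatomy"][p.label] = p.anatomy_value
        tables["mu"][p.label] = p.uptake_mean
        tables["sb"][p.label] = p.between_scan_sd
        tables["sw"][p.label] = p.within_scan_sd
    return tables


def synthesize_pair(
    labels: Volume,
    params: Sequence[RegionParams] = DEFAULT_REGIONS,
    seed: int | np.random.Generator = 0,
    anatomy_noise_sd: float = 15.0,
) -> tuple[VolumePair, GroundTruthStats]:
    """Draw one normal scan from the phantom population.

    Anatomy = region HU value + Gaussian texture noise.  Function =
    ``mu_r + b_r + e`` with ``b_r`` drawn once per scan per region and
    ``e`` per voxel, clipped at 0.  The returned ground truth carries the
    marginal ``mu_r`` and ``sigma_r`` per voxel.
    """
    rng = np.random.default_rng(seed)
    lab = labels.data
    t = _param_lookup(params, lab)

    anatomy = t["anatomy"][lab] + rng.normal(0.0, anatomy_noise_sd, lab.shape)
    # one offset per region id (including ids absent from this scan, so the
    # stream layout does not depend on which labels happen to be present)
    b = rng.normal(0.0, 1.0, t["sb"].shape) * t["sb"]
    function = t["mu"][lab] + b[lab] + rng.normal(0.0, 1.0, lab.shape) * t["sw"][lab]
    np.clip(function, 0.0, None, out=function)

    pair = VolumePair(
        anatomy=Volume(anatomy, labels.spacing, labels.origin),
        function=Volume(function, labels.spacing, labels.origin),
    )
    stats = GroundTruthStats(
        mean_volume=t["mu"][lab],
        sd_volume=np.hypot(t["sb"], t["sw"])[lab],
    )
    return pair, stats


# annotated lesion voxels are those receiving more than half of the peak
# added value: the mask is exactly the half-maximum ball of radius radius_mm.
# (A lower fraction would annotate rim voxels whose added signal is a small
# fraction of the local noise SD -- undetectable by construction, by any
# method -- so voxel-level evaluation would measure the annotation rule,
# not the detector.)
MASK_FRACTION = 0.50
_MASK_RADIUS_FACTOR = 1.0  # mask radius / radius_mm at the 50% rule
_SUPPORT_FACTOR = 3.0  # bump truncated at 3 x radius_mm


def inject_lesions(
    pair: VolumePair,
    labels: Volume,
    spec: LesionSpec | Sequence[LesionSpec],
    params: Sequence[RegionParams] = DEFAULT_REGIONS,
    seed: int | np.random.Generator = 0,
    max_retries: int = 200,
) -> tuple[VolumePair, LesionAnnotation]:
    """Add focal Gaussian uptake lesions and return the annotated pair.

    Each lesion is a spherical Gaussian bump with half-maximum at
    ``radius_mm`` and peak ``amplitude_sd * sigma_r`` of the host region,
    added to the function channel only, centred uniformly over the
    region's interior (>= radius_mm from the region boundary).  The
    annotation mask collects voxels receiving more than half of the peak
    (the half-maximum ball); the centroid is the unweighted mean of mask
    voxel centers in mm.
    """
    specs = [spec] if isinstance(spec, LesionSpec) else list(spec)
    sd_by_label = {p.label: p.total_sd for p in params}
    rng = np.random.default_rng(seed)
    pair.validate_aligned()
    if pair.anatomy.shape != labels.shape:
        raise ValueError("labels shape does not match pair")

    function = pair.function.data.copy()
    spacing = np.asarray(labels.spacing)
    origin = np.asarray(labels.origin)
    mask = np.zeros(labels.shape, dtype=np.uint8)
    lesions: list[LesionInfo] = []
    placed_centers: list[np.ndarray] = []
    lesion_id = 0

    for sp in specs:
        region = labels.data == sp.region_label
        if not region.any():
            raise ValueError(f"region label {sp.region_label} not present in labels")
        # interior: at least radius_mm from the region boundary, in mm
        dist = ndimage.distance_transform_edt(region, sampling=spacing)
        interior = np.argwhere(dist >= sp.radius_mm)
        if len(interior) == 0:
            raise PlacementError(
                f"region {sp.region_label} too small for radius {sp.radius_mm} mm"
            )
        sigma_r = sd_by_label[sp.region_label]
        min_sep = 2.0 * _MASK_RADIUS_FACTOR * sp.radius_mm
        for _ in range(sp.count):
            lesion_id += 1
            for attempt in range(max_retries):
                center_idx = interior[rng.integers(len(interior))]
                center_mm = origin + center_idx * spacing
                if all(
                    np.linalg.norm(center_mm - c) > min_sep for c in placed_centers
                ):
                    break
            else:
                raise PlacementError(
                    f"could not place lesion {lesion_id} without overlap "
                    f"after {max_retries} retries"
                )
            placed_centers.append(center_mm)

            amp = sp.amplitude_sd * sigma_r
            gamma = sp.radius_mm / np.sqrt(2.0 * np.log(2.0))
            support = _SUPPORT_FACTOR * sp.radius_mm
            lo = np.maximum(np.floor((center_mm - origin - support) / spacing), 0).astype(int)
            hi = np.minimum(
                np.ceil((center_mm - origin + support) / spacing).astype(int) + 1,
                labels.shape,
            )
            sl = tuple(slice(l, h) for l, h in zip(lo, hi))
            grids = np.meshgrid(
                *[origin[a] + np.arange(lo[a], hi[a]) * spacing[a] for a in range(3)],
                indexing="ij",
            )
            d2 = sum((g - c) ** 2 for g, c in zip(grids, center_mm))
            bump = amp * np.exp(-d2 / (2.0 * gamma**2))
            bump[d2 > support**2] = 0.0
            function[sl] += bump
            lesion_mask = bump > MASK_FRACTION * amp
            mask_idx = np.argwhere(lesion_mask) + lo
            mask[sl][lesion_mask] = lesion_id
            centroid = origin + mask_idx.mean(axis=0) * spacing
            lesions.append(
                LesionInfo(
                    lesion_id=lesion_id,
                    centroid_mm=tuple(float(c) for c in centroid),
                    peak_added_suv=float(amp),
                    region_label=sp.region_label,
                )
            )

    out_pair = VolumePair(
        anatomy=pair.anatomy.copy(),
        function=Volume(function, pair.function.spacing, pair.function.origin),
    )
    annotation = LesionAnnotation(
        mask=Volume(mask, labels.spacing, labels.origin), lesions=lesions
    )
    return out_pair, annotation


@dataclasses.dataclass
class PhantomConfig:
    """Cohort-level phantom configuration."""

    shape: tuple[int, int, int] = (64, 64, 24)
    spacing: tuple[float, float, float] = (3.0, 3.0, 3.0)
    regions: tuple[RegionParams, ...] = DEFAULT_REGIONS
    lesions: tuple[LesionSpec, ...] = (
        LesionSpec(region_label=LUNG, radius_mm=4.0, amplitude_sd=5.0, count=1),
        LesionSpec(region_label=HEART, radius_mm=4.0, amplitude_sd=5.0, count=1),
    )
    n_train: int = 60
    n_eval_normal: int = 6
    n_eval_abnormal: int = 12
    anatomy_noise_sd: float = 15.0
    jitter: float = 0.05


def scan_seed(seed: int, index: int) -> int:
    """Deterministic per-scan sub-seed (stable across runs and platforms)."""
    return int(np.random.SeedSequence([seed, index]).generate_state(1)[0] % (2**31))


def make_scan(
    config: PhantomConfig, seed: int, index: int, with_lesions: bool
) -> tuple[VolumePair, GroundTruthStats, LesionAnnotation | None, Volume]:
    """Generate one scan (pair, ground truth, optional annotation, labels)."""
    s = scan_seed(seed, index)
    labels = make_phantom_labels(
        config.shape, np.random.default_rng([s, 0]), config.spacing, config.jitter
    )
    pair, stats = synthesize_pair(
        labels, config.regions, np.random.default_rng([s, 1]), config.anatomy_noise_sd
    )
    annotation = None
    if with_lesions:
        pair, annotation = inject_lesions(
            pair, labels, config.lesions, config.regions, np.random.default_rng([s, 2])
        )
    return pair, stats, annotation, labels


def generate_dataset(
    config: PhantomConfig,
    out_dir: str | Path,
    seed: int,
    overwrite: bool = False,
) -> pd.DataFrame:
    """Write a train/eval phantom cohort to disk and return the manifest.

    Layout: ``<out>/<role>/scan_<id>_{ct,pet}.nii.gz`` plus
    ``..._mask.nii.gz`` and a ``lesions.csv`` for abnormal scans, and a
    cohort ``manifest.csv`` (scan_id, role, n_lesions, seed).  Fully
    reproducible from (config, seed).
    """
    out_dir = Path(out_dir)
    if out_dir.exists() and any(out_dir.iterdir()) and not overwrite:
        raise FileExistsError(f"{out_dir} is not empty; pass overwrite=True")
    roles = (
        [("train", False)] * config.n_train
        + [("eval_normal", False)] * config.n_eval_normal
        + [("eval_abnormal", True)] * config.n_eval_abnormal
    )
    rows = []
    lesion_rows = []
    for index, (role, with_lesions) in enumerate(roles):
        scan_id = f"scan_{index:04d}"
        pair, _, annotation, _ = make_scan(config, seed, index, with_lesions)
        role_dir = out_dir / role
        role_dir.mkdir(parents=True, exist_ok=True)
        write_volume(pair.anatomy, role_dir / f"{scan_id}_ct.nii.gz")
        write_volume(pair.function, role_dir / f"{scan_id}_pet.nii.gz")
        n_lesions = 0
        if annotation is not None:
            write_volume(annotation.mask, role_dir / f"{scan_id}_mask.nii.gz")
            n_lesions = len(annotation.lesions)
            for les in annotation.lesions:
                lesion_rows.append(
                    {
                        "scan_id": scan_id,
                        "lesion_id": les.lesion_id,
                        "centroid_x_mm": les.centroid_mm[0],
                        "centroid_y_mm": les.centroid_mm[1],
                        "centroid_z_mm": les.centroid_mm[2],
                        "peak_added_suv": les.peak_added_suv,
                        "region_label": les.region_label,
                    }
                )
        rows.append(
            {
                "scan_id": scan_id,
                "role": role,
                "n_lesions": n_lesions,
                "seed": scan_seed(seed, index),
            }
        )
    manifest = pd.DataFrame(rows)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    pd.DataFrame(
        lesion_rows,
        columns=[
            "scan_id",
            "lesion_id",
            "centroid_x_mm",
            "centroid_y_mm",
            "centroid_z_mm",
            "peak_added_suv",
            "region_label",
        ],
    ).to_csv(out_dir / "lesions.csv", index=False, float_format="%.10g")
    return manifest
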