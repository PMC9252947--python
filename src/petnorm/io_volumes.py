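"""NIfTI volume I/O, isotropic resampling, and axial slice iteration.

Conventions
-----------
Arrays are indexed ``(x, y, z)`` with the axial (slice) axis last.  The
physical center of voxel ``(i, j, k)`` is ``origin + index * spacing``,
in millimetres; all distances downstream (e.g. the lesion-matching
radius) are computed in this physical frame.

Intensity volumes are resampled with linear interpolation, label/mask
volumes with nearest-neighbour, so that label semantics survive
resampling.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Iterator
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage


class FormatError(ValueError):
    """Raised when a file on disk is not a 3-D scalar volume."""


@dataclasses.dataclass
class Volume:
    """A 3-D scalar grid with physical geometry.

    Parameters
    ----------
    data
        3-D array; SUV for functional volumes, HU-like values for
        anatomical volumes, small integer labels for masks.
    spacing
        Per-axis voxel size in mm, strictly positive.
    origin
        Physical position of voxel (0, 0, 0) in mm.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise FormatError(f"expected a 3-D volume, got ndim={self.data.ndim}")
        if min(self.data.shape) < 1:
            raise ValueError(f"degenerate volume shape {self.data.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or len(self.origin) != 3:
            raise ValueError("spacing and origin must have length 3")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def voxel_centers_mm(self, indices: np.ndarray) -> np.ndarray:
        """Physical centers (mm) of the given (n, 3) voxel indices."""
        idx = np.atleast_2d(np.asarray(indices, dtype=float))
        return np.asarray(self.origin) + idx * np.asarray(self.spacing)

    def copy(self) -> "Volume":
        return Volume(self.data.copy(), self.spacing, self.origin)


@dataclasses.dataclass
class VolumePair:
    """Co-registered anatomical and functional volumes of one scan."""

    anatomy: Volume
    function: Volume

    def validate_aligned(self) -> None:
        if self.anatomy.shape != self.function.shape:
            raise ValueError(
                f"channel shape mismatch: anatomy {self.anatomy.shape} "
                f"vs function {self.function.shape}"
            )
        if not np.allclose(self.anatomy.spacing, self.function.spacing, atol=1e-9):
            raise ValueError("channel spacing mismatch")
        if not np.allclose(self.anatomy.origin, self.function.origin, atol=1e-9):
            raise ValueError("channel origin mismatch")


@dataclasses.dataclass
class SlicePair:
    """One axial slice of a co-registered pair."""

    anatomy_slice: np.ndarray
    function_slice: np.ndarray
    axial_index: int


def read_volume(path: str | Path) -> Volume:
    """Read a 3-D NIfTI file into a :class:`Volume`.

    Spacing is taken from the header zooms and the origin from the affine
    translation; voxel values are returned unchanged.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if data.ndim != 3:
        raise FormatError(f"{path}: expected 3-D image, got ndim={data.ndim}")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    origin = tuple(float(t) for t in img.affine[:3, 3])
    return Volume(np.asarray(data, dtype=np.float64), spacing, origin)


def write_volume(vol: Volume, path: str | Path) -> None:
    """Write a :class:`Volume` to NIfTI, encoding spacing and origin."""
    path = Path(path)
    if not path.parent.exists():
        raise IOError(f"parent directory does not exist: {path.parent}")
    affine = np.diag(list(vol.spacing) + [1.0])
    affine[:3, 3] = vol.origin
    img = nib.Nifti1Image(np.asarray(vol.data, dtype=np.float64), affine)
    img.header.set_zooms(vol.spacing)
    nib.save(img, str(path))


def resample_isotropic(
    vol: Volume, target_mm: float, interpolation: str = "linear"
) -> Volume:
    """Resample a volume to isotropic ``target_mm`` spacing.

    Output voxel centers sit at ``origin + i * target_mm``; the output
    extent covers the input physical extent (``ceil(extent / target)``
    voxels per axis).  Coordinates outside the input grid clamp to the
    edge value.  ``interpolation`` is ``"linear"`` for intensity volumes
    and ``"nearest"`` for label masks.
    """
    if target_mm <= 0:
        raise ValueError(f"target_mm must be positive, got {target_mm}")
    if interpolation not in ("linear", "nearest"):
        raise ValueError(f"unknown interpolation {interpolation!r}")
    order = 1 if interpolation == "linear" else 0
    in_shape = np.array(vol.shape)
    spacing = np.array(vol.spacing)
    out_shape = np.ceil(in_shape * spacing / target_mm).astype(int)
    out_shape = np.maximum(out_shape, 1)
    # output voxel i maps to fractional input index i * target / spacing
    axes = [np.arange(n) * target_mm / s for n, s in zip(out_shape, spacing)]
    coords = np.meshgrid(*axes, indexing="ij")
    out = ndimage.map_coordinates(
        np.asarray(vol.data, dtype=np.float64),
        np.stack(coords),
        order=order,
        mode="nearest",
    )
    if order == 0:
        out = out.astype(vol.data.dtype)
    return Volume(out, (target_mm,) * 3, vol.origin)


def resample_pair(pair: VolumePair, target_mm: float) -> VolumePair:
    """Resample both channels of a pair to a common isotropic grid."""
    return VolumePair(
        anatomy=resample_isotropic(pair.anatomy, target_mm, "linear"),
        function=resample_isotropic(pair.function, target_mm, "linear"),
    )


def iter_axial_slices(pair: VolumePair) -> Iterator[SlicePair]:
    """Yield one :class:`SlicePair` per axial index, in order.

    Stacking the yielded ``function_slice`` arrays along the last axis
    reconstructs the function volume exactly.
    """
    pair.validate_aligned()
    for k in range(pair.anatomy.shape[2]):
        yield SlicePair(
            anatomy_slice=pair.anatomy.data[:, :, k],
            function_slice=pair.function.data[:, :, k],
            axial_index=k,
        )
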