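"""Reading, writing and canonicalizing 3D brain volumes and lesion masks.

All arrays in this package follow a fixed canonical axis order

    axis 0 : inferior -> superior   (axial slicing axis)
    axis 1 : posterior -> anterior  (coronal slicing axis)
    axis 2 : left -> right          (sagittal slicing axis)

so a full-scale MNI-gridded scan is ``(192, 224, 192)``.  NIfTI files of any
orientation are reoriented to this order on load via their header codes.
Registration to MNI space and skull stripping are upstream responsibilities:
this module validates aligned inputs, it never resamples them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

#: canonical anatomical axis labels, in array-axis order
CANONICAL_AXES = ("inferior-superior", "posterior-anterior", "left-right")

#: array axis along which a left-right flip acts
LR_AXIS = 2

#: full-scale MNI-conformed grid used by the segmentation system
FULL_GRID_SHAPE = (192, 224, 192)


class VolumeValidationError(ValueError):
    """Raised when a volume or mask violates a contract of this module."""


class OrientationError(VolumeValidationError):
    """Raised when a file's anatomical orientation cannot be resolved."""


@dataclass
class BrainVolume:
    """A skull-stripped, atlas-aligned 3D intensity volume.

    Parameters
    ----------
    data
        3D float array of intensities in canonical axis order.
    spacing
        Voxel size in mm per canonical axis.
    affine
        Optional 4x4 voxel-to-world matrix of the canonical array, kept so
        masks can be written back into the source geometry.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: np.ndarray | None = None
    axis_labels: tuple[str, str, str] = CANONICAL_AXES

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise VolumeValidationError(
                f"expected a 3D volume, got {self.data.ndim} dimensions"
            )
        if any(s <= 0 for s in self.spacing):
            raise VolumeValidationError(f"voxel spacing must be positive: {self.spacing}")
        bad = np.count_nonzero(~np.isfinite(self.data))
        if bad:
            raise VolumeValidationError(f"volume contains {bad} non-finite voxels")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass
class LesionMask:
    """A binary lesion mask aligned voxel-for-voxel with a :class:`BrainVolume`."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise VolumeValidationError(
                f"expected a 3D mask, got {self.data.ndim} dimensions"
            )
        vals = np.unique(self.data)
        if not np.all(np.isin(vals, (0, 1))):
            raise VolumeValidationError("mask voxels must all be 0 or 1")
        self.data = self.data.astype(np.uint8)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def foreground_count(self) -> int:
        return int(self.data.sum())


@dataclass
class GridSpec:
    """Target voxel grid every volume is conformed to before entering the CNNs.

    ``divisibility`` guards the encoder/decoder contract: four 2x2 pooling
    steps shrink each in-plane axis by 16, so each spatial dim must divide 16.
    """

    target_shape: tuple[int, int, int] = FULL_GRID_SHAPE
    divisibility: int = 16

    def __post_init__(self) -> None:
        if any(s % self.divisibility for s in self.target_shape):
            raise VolumeValidationError(
                f"grid dims {self.target_shape} must each be divisible by "
                f"{self.divisibility}"
            )


def _canonical_from_nifti(img: nib.Nifti1Image) -> tuple[np.ndarray, tuple, np.ndarray]:
    """Reorient a loaded NIfTI to canonical (IS, PA, LR) axis order."""
    try:
        ras = nib.as_closest_canonical(img)
    except Exception as exc:  # pragma: no cover - nibabel raises various types
        raise OrientationError(f"cannot resolve orientation: {exc}") from exc
    data = np.asanyarray(ras.dataobj)
    if data.ndim != 3:
        raise VolumeValidationError(f"expected a 3D image, file has {data.ndim} dims")
    # RAS array axes are (LR, PA, IS); canonical order is the reverse.
    data = np.transpose(data, (2, 1, 0))
    zooms = ras.header.get_zooms()[:3]
    spacing = (float(zooms[2]), float(zooms[1]), float(zooms[0]))
    # voxel-to-world affine of the transposed array
    perm = np.zeros((4, 4))
    perm[3, 3] = 1.0
    perm[0, 2] = perm[1, 1] = perm[2, 0] = 1.0
    affine = ras.affine @ perm
    return data, spacing, affine


def read_volume(path: str | Path) -> BrainVolume:
    """Read a 3D NIfTI-1 volume (optionally gzipped) into canonical order.

    Raises
    ------
    FileNotFoundError
        if *path* does not exist.
    VolumeValidationError
        for non-3D images or non-finite voxel data.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data, spacing, affine = _canonical_from_nifti(img)
    data = np.asarray(data, dtype=np.float32)
    return BrainVolume(data=data, spacing=spacing, affine=affine)


def read_mask(path: str | Path, threshold: float = 0.5) -> LesionMask:
    """Read a NIfTI mask, binarizing at *threshold* (values >= threshold -> 1)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data, spacing, affine = _canonical_from_nifti(img)
    bad = np.count_nonzero(~np.isfinite(data))
    if bad:
        raise VolumeValidationError(f"mask contains {bad} non-finite voxels")
    binary = (np.asarray(data, dtype=np.float64) >= threshold).astype(np.uint8)
    return LesionMask(data=binary, spacing=spacing, affine=affine)


def write_mask(mask: LesionMask, reference: BrainVolume, path: str | Path) -> None:
    """Write *mask* as NIfTI-1 in the geometry of *reference*."""
    if mask.shape != reference.shape:
        raise VolumeValidationError(
            f"mask shape {mask.shape} != reference shape {reference.shape}"
        )
    _write_canonical(mask.data.astype(np.uint8), reference, path)


def write_volume(vol: BrainVolume, path: str | Path) -> None:
    """Write a canonical-order volume back to NIfTI-1."""
    _write_canonical(np.asarray(vol.data, dtype=np.float32), vol, path)


def _write_canonical(data: np.ndarray, geom: BrainVolume | LesionMask, path) -> None:
    # undo the canonical (IS, PA, LR) -> RAS (LR, PA, IS) transpose
    ras_data = np.transpose(data, (2, 1, 0))
    if geom.affine is not None:
        perm = np.zeros((4, 4))
        perm[3, 3] = 1.0
        perm[0, 2] = perm[1, 1] = perm[2, 0] = 1.0
        affine = geom.affine @ np.linalg.inv(perm)
    else:
        affine = np.diag([geom.spacing[2], geom.spacing[1], geom.spacing[0], 1.0])
    img = nib.Nifti1Image(ras_data, affine)
    img.header.set_zooms((geom.spacing[2], geom.spacing[1], geom.spacing[0]))
    nib.save(img, str(path))


def _crop_pad_1d(extent: int, target: int) -> tuple[slice, slice]:
    """Source and destination slices for symmetric center crop/pad on one axis."""
    if extent >= target:
        lo = (extent - target) // 2
        return slice(lo, lo + target), slice(0, target)
    lo = (target - extent) // 2
    return slice(0, extent), slice(lo, lo + extent)


def conform_to_grid(vol: BrainVolume, grid: GridSpec, fill: float = 0.0) -> BrainVolume:
    """Center-crop / symmetrically pad *vol* to ``grid.target_shape``.

    Voxel values inside the overlap region are preserved exactly; padded
    voxels take *fill*.
    """
    src = vol.data
    out = np.full(grid.target_shape, fill, dtype=src.dtype)
    slices = [_crop_pad_1d(src.shape[a], grid.target_shape[a]) for a in range(3)]
    out[slices[0][1], slices[1][1], slices[2][1]] = src[
        slices[0][0], slices[1][0], slices[2][0]
    ]
    return BrainVolume(data=out, spacing=vol.spacing, affine=vol.affine)


def conform_mask_to_grid(mask: LesionMask, grid: GridSpec) -> LesionMask:
    """Mask counterpart of :func:`conform_to_grid` (fill is always 0)."""
    as_vol = BrainVolume(data=mask.data.astype(np.float32), spacing=mask.spacing,
                         affine=mask.affine)
    conformed = conform_to_grid(as_vol, grid, fill=0.0)
    return LesionMask(data=conformed.data.astype(np.uint8), spacing=mask.spacing,
                      affine=mask.affine)


def flip_lr(vol: BrainVolume) -> BrainVolume:
    """Mirror a volume across the mid-sagittal plane.

    The flipped scan serves as the auxiliary input modality when no FLAIR is
    available: homologous right-hemisphere tissue gives the network a healthy
    reference for each left-hemisphere location.
    """
    if vol.axis_labels[LR_AXIS] != "left-right":
        raise OrientationError(
            f"axis {LR_AXIS} is {vol.axis_labels[LR_AXIS]!r}, not left-right"
        )
    return BrainVolume(
        data=np.flip(vol.data, axis=LR_AXIS).copy(),
        spacing=vol.spacing,
        affine=vol.affine,
        axis_labels=vol.axis_labels,
    )
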