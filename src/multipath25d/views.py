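"""The nine (plane x normalization) views feeding the per-path networks.

A volume is sliced along each of the three anatomical planes and each slice
stack is intensity-standardized in one of three ways:

``in_plane``
    every 2D slice is z-scored independently over its foreground voxels;
``across_third``
    for every in-slice pixel position, the 1D intensity profile along the
    slicing axis is z-scored over its foreground entries;
``both``
    in-plane first, then across the third axis.

The Cartesian product gives nine distinct path inputs per volume pair.
Foreground means "not exactly zero": skull-stripped scans carry an exact-zero
background which must neither dilute the moments nor be moved off zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .volume_io import BrainVolume, VolumeValidationError

#: guard below which a slice/profile is treated as constant and zeroed out
_SD_FLOOR = 1e-8


class PlaneId(str, Enum):
    """Anatomical slicing plane, mapped to a canonical array axis."""

    AXIAL = "axial"       # slices along axis 0 (inferior-superior)
    CORONAL = "coronal"   # slices along axis 1 (posterior-anterior)
    SAGITTAL = "sagittal" # slices along axis 2 (left-right)

    @property
    def axis(self) -> int:
        return {"axial": 0, "coronal": 1, "sagittal": 2}[self.value]


class NormScheme(str, Enum):
    IN_PLANE = "in_plane"
    ACROSS_THIRD = "across_third"
    BOTH = "both"


@dataclass
class PathInput:
    """Normalized slice-stack pair for one (plane, scheme) path.

    ``primary_stack`` and ``auxiliary_stack`` are ``(n_slices, h, w)`` arrays;
    ``slice_index_map[k]`` is the source-volume index of stack position k.
    """

    plane: PlaneId
    scheme: NormScheme
    primary_stack: np.ndarray
    auxiliary_stack: np.ndarray
    slice_index_map: np.ndarray

    def __post_init__(self) -> None:
        if self.primary_stack.shape != self.auxiliary_stack.shape:
            raise VolumeValidationError(
                "primary and auxiliary stacks must have identical shape, got "
                f"{self.primary_stack.shape} vs {self.auxiliary_stack.shape}"
            )
        if len(self.slice_index_map) != self.primary_stack.shape[0]:
            raise VolumeValidationError("slice_index_map length != stack length")


def extract_slices(vol: BrainVolume | np.ndarray, plane: PlaneId) -> np.ndarray:
    """Return the volume as an ordered ``(n_slices, h, w)`` stack for *plane*."""
    data = vol.data if isinstance(vol, BrainVolume) else np.asarray(vol)
    return np.moveaxis(data, plane.axis, 0)


def restack_slices(stack: np.ndarray, plane: PlaneId) -> np.ndarray:
    """Inverse of :func:`extract_slices`: rebuild the 3D array."""
    return np.moveaxis(stack, 0, plane.axis)


def normalize_in_plane(stack: np.ndarray) -> np.ndarray:
    """Z-score each slice over its nonzero voxels; zeros and constant slices stay zero."""
    stack = np.asarray(stack, dtype=np.float32)
    out = np.zeros_like(stack)
    for k in range(stack.shape[0]):
        sl = stack[k]
        fg = sl != 0
        n = int(fg.sum())
        if n == 0:
            continue
        vals = sl[fg]
        mu = vals.mean(dtype=np.float64)
        sd = vals.std(dtype=np.float64)
        if sd < _SD_FLOOR:
            continue
        out[k][fg] = ((vals - mu) / sd).astype(np.float32)
    return out


def normalize_across_third(stack: np.ndarray) -> np.ndarray:
    """Z-score each through-plane profile over its nonzero entries.

    For pixel position (i, j) the 1D profile ``stack[:, i, j]`` is
    standardized; profiles that are constant (or all background) map to zero.
    """
    stack = np.asarray(stack, dtype=np.float32)
    fg = stack != 0
    n = fg.sum(axis=0)                       # (h, w) foreground counts
    vals = np.where(fg, stack, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mu = vals.sum(axis=0, dtype=np.float64) / n
        var = (np.where(fg, (stack - mu) ** 2, 0.0).sum(axis=0, dtype=np.float64)) / n
        sd = np.sqrt(var)
        z = (stack - mu) / sd
    keep = fg & (n > 0) & (sd >= _SD_FLOOR)
    out = np.where(keep, z, 0.0).astype(np.float32)
    return out


_SCHEME_FN = {
    NormScheme.IN_PLANE: normalize_in_plane,
    NormScheme.ACROSS_THIRD: normalize_across_third,
    NormScheme.BOTH: lambda s: normalize_across_third(normalize_in_plane(s)),
}


def normalize_stack(stack: np.ndarray, scheme: NormScheme) -> np.ndarray:
    return _SCHEME_FN[NormScheme(scheme)](stack)


def build_nine_views(primary: BrainVolume, auxiliary: BrainVolume) -> list[PathInput]:
    """Build all nine path inputs for a co-registered volume pair.

    *auxiliary* is either the left-right-mirrored primary scan or a second
    modality (FLAIR); both modalities receive the same plane and scheme.
    """
    if primary.shape != auxiliary.shape:
        raise VolumeValidationError(
            f"modality shapes differ: {primary.shape} vs {auxiliary.shape}"
        )
    views: list[PathInput] = []
    for plane in PlaneId:
        p_stack = extract_slices(primary, plane)
        a_stack = extract_slices(auxiliary, plane)
        idx = np.arange(p_stack.shape[0])
        for scheme in NormScheme:
            views.append(
                PathInput(
                    plane=plane,
                    scheme=scheme,
                    primary_stack=normalize_stack(p_stack, scheme),
                    auxiliary_stack=normalize_stack(a_stack, scheme),
                    slice_index_map=idx.copy(),
                )
            )
    return views


#: canonical ordering of the nine paths, used for checkpoint naming and stacking
ALL_PATHS: list[tuple[PlaneId, NormScheme]] = [
    (plane, scheme) for plane in PlaneId for scheme in NormScheme
]
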