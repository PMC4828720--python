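"""Grid-aware volumetric containers and morphology/distance primitives.

Conventions used throughout the package:

* Arrays are indexed ``(x, y, z)`` with ``z`` the optical-section axis.
* Voxel coordinates are 0-based; a voxel's physical position is its center.
* All public distances are in micrometres (μm) and volumes in μm³, never in
  voxel units — the voxel spacing may be anisotropic (z-steps of light-sheet
  or multiphoton stacks are typically coarser than the in-plane pitch).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

__all__ = [
    "VoxelGrid",
    "IntensityVolume",
    "MultiChannelVolume",
    "BinaryMask",
    "LabelVolume",
    "EmptyMaskError",
    "voxel_volume",
    "connectivity_structure",
    "connected_components",
    "distance_transform",
    "dilate_by_distance",
]

# Absolute slack (μm) absorbing floating-point error when thresholding
# Euclidean distance fields at an exact radius.
_DIST_EPS = 1e-9


class EmptyMaskError(ValueError):
    """Raised when an operation needs a non-empty reference voxel set."""


@dataclass(frozen=True)
class VoxelGrid:
    """A regular anisotropic 3D voxel lattice.

    Parameters
    ----------
    shape
        Number of voxels along (x, y, z); each entry ≥ 1.
    spacing
        Physical voxel pitch along (x, y, z) in μm; each entry > 0.
    """

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        shape = tuple(int(n) for n in self.shape)
        spacing = tuple(float(s) for s in self.spacing)
        if len(shape) != 3 or len(spacing) != 3:
            raise ValueError("shape and spacing must be length-3 triples")
        if any(n < 1 for n in shape):
            raise ValueError(f"all shape entries must be >= 1, got {shape}")
        if any(not np.isfinite(s) or s <= 0 for s in spacing):
            raise ValueError(f"all spacing entries must be > 0, got {spacing}")
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "spacing", spacing)

    @property
    def n_voxels(self) -> int:
        nx, ny, nz = self.shape
        return nx * ny * nz


def voxel_volume(grid: VoxelGrid) -> float:
    """Physical volume of one voxel in μm³ (product of the spacings)."""
    sx, sy, sz = grid.spacing
    return sx * sy * sz


def _check_array(grid: VoxelGrid, values: np.ndarray, name: str) -> np.ndarray:
    values = np.asarray(values)
    if values.shape != grid.shape:
        raise ValueError(
            f"{name} shape {values.shape} does not match grid shape {grid.shape}"
        )
    return values


@dataclass
class IntensityVolume:
    """One imaging channel (e.g. K8, GFAP, EdU, DAPI, vessel label).

    Values are finite and non-negative scalar intensities on ``grid``.
    """

    grid: VoxelGrid
    values: np.ndarray
    channel_name: str = ""

    def __post_init__(self) -> None:
        self.values = _check_array(self.grid, self.values, "values")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("intensity values must be finite")
        if np.any(self.values < 0):
            raise ValueError("intensity values must be non-negative")


@dataclass
class MultiChannelVolume:
    """Co-registered channels sharing one voxel grid, with unique names."""

    channels: list[IntensityVolume]

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("at least one channel required")
        grid = self.channels[0].grid
        names = [c.channel_name for c in self.channels]
        if len(set(names)) != len(names):
            raise ValueError(f"channel names must be unique, got {names}")
        for c in self.channels:
            if c.grid != grid:
                raise ValueError("all channels must share one identical grid")

    @property
    def grid(self) -> VoxelGrid:
        return self.channels[0].grid

    @property
    def channel_names(self) -> list[str]:
        return [c.channel_name for c in self.channels]

    def __getitem__(self, name: str) -> IntensityVolume:
        for c in self.channels:
            if c.channel_name == name:
                return c
        raise KeyError(name)


@dataclass
class BinaryMask:
    """A boolean voxel set annotating a volume on the same grid."""

    grid: VoxelGrid
    member: np.ndarray

    def __post_init__(self) -> None:
        member = _check_array(self.grid, self.member, "member")
        self.member = member.astype(bool, copy=False)

    @property
    def count(self) -> int:
        """Number of member voxels."""
        return int(np.count_nonzero(self.member))

    @property
    def volume_um3(self) -> float:
        """Physical volume of the voxel set in μm³."""
        return self.count * voxel_volume(self.grid)


@dataclass
class LabelVolume:
    """Non-negative integer labels per voxel; 0 is background."""

    grid: VoxelGrid
    label: np.ndarray

    def __post_init__(self) -> None:
        label = _check_array(self.grid, self.label, "label")
        if label.dtype.kind not in "iu":
            raise ValueError("labels must be integer-valued")
        if np.any(label < 0):
            raise ValueError("labels must be non-negative")
        self.label = label

    @property
    def n_labels(self) -> int:
        return int(self.label.max(initial=0))


def connectivity_structure(connectivity: int) -> np.ndarray:
    """3×3×3 structuring element for 6-, 18- or 26-connectivity."""
    try:
        rank = {6: 1, 18: 2, 26: 3}[connectivity]
    except KeyError:
        raise ValueError(
            f"connectivity must be one of 6, 18, 26; got {connectivity!r}"
        ) from None
    return ndi.generate_binary_structure(3, rank)


def connected_components(mask: BinaryMask, connectivity: int = 26) -> LabelVolume:
    """Label connected components of ``mask``.

    Labels are 1..K assigned deterministically by the scan order (C order of
    the (x, y, z) array) of each component's first voxel; label 0 exactly
    where the mask is false.
    """
    structure = connectivity_structure(connectivity)
    raw, n = ndi.label(mask.member, structure=structure)
    if n == 0:
        return LabelVolume(mask.grid, raw)
    # Relabel by first occurrence in scan order so ids are reproducible
    # regardless of the labeling backend's internal order.
    flat = raw.ravel()
    labels, first = np.unique(flat, return_index=True)
    keep = labels > 0
    order = np.argsort(first[keep])
    remap = np.zeros(int(labels.max()) + 1, dtype=raw.dtype)
    remap[labels[keep][order]] = np.arange(1, int(keep.sum()) + 1)
    return LabelVolume(mask.grid, remap[raw])


def distance_transform(mask: BinaryMask) -> np.ndarray:
    """Euclidean distance (μm) from every voxel to the nearest mask voxel.

    Uses the anisotropic voxel spacing; the field is 0 on the mask itself.

    Raises
    ------
    EmptyMaskError
        If the mask has no member voxels (no reference set).
    """
    if mask.count == 0:
        raise EmptyMaskError("distance_transform needs a non-empty mask")
    return ndi.distance_transform_edt(~mask.member, sampling=mask.grid.spacing)


def dilate_by_distance(mask: BinaryMask, radius: float) -> BinaryMask:
    """Spherical (physical-distance) dilation of a mask by ``radius`` μm.

    Implemented as a threshold of the anisotropy-aware Euclidean distance
    transform rather than a discrete structuring element, so the ball is
    exact on anisotropic grids. Radius 0 returns the input mask; the result
    always supersets the input.
    """
    if radius < 0:
        raise ValueError(f"radius must be >= 0, got {radius}")
    if mask.count == 0 or radius == 0:
        return BinaryMask(mask.grid, mask.member.copy())
    dist = distance_transform(mask)
    return BinaryMask(mask.grid, dist <= radius + _DIST_EPS)
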