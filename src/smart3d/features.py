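"""Per-voxel appearance/texture features and the multi-channel feature vector.

For every channel and every scale σ (μm) the volume is Gaussian-smoothed
(anisotropy-corrected: σ in voxels differs per axis) and four feature
families are computed, 8 features per channel per scale:

* intensity (smoothed),
* gradient magnitude,
* the three eigenvalues of the Hessian matrix,
* the three eigenvalues of the structure tensor (first-derivative outer
  products integrated at the same scale).

All derivatives are taken in physical units (per μm), so features are
comparable across anisotropic grids. Eigenvalue triples are sorted by
signed value, descending, which makes them invariant to axis permutation.
Concatenating the per-channel stacks yields the multi-channel feature
vector (MFV) fed to the voxel classifiers.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
from scipy import ndimage as ndi

from .core import IntensityVolume, VoxelGrid

__all__ = ["FeatureStack", "DEFAULT_SCALES_UM", "extract_channel_features", "build_mfv"]

#: Default feature scales in μm; single-scale mode ([1.0]) reproduces the
#: literal 8-feature-per-channel MFV.
DEFAULT_SCALES_UM: tuple[float, ...] = (1.0, 2.0, 4.0)

# Wider kernel support than the scipy default so derivative kernels sum
# to ~0 and constant regions yield ~0 differential features.
_TRUNCATE = 6.0

_FAMILIES = ("intensity", "gradmag", "hess1", "hess2", "hess3", "st1", "st2", "st3")


class FeatureStack:
    """Per-voxel feature vectors on a grid.

    ``vectors`` has shape ``grid.shape + (n_features,)`` and
    ``feature_names`` names each trailing-axis entry.
    """

    def __init__(self, grid: VoxelGrid, vectors: np.ndarray, feature_names: Sequence[str]):
        vectors = np.asarray(vectors)
        if vectors.shape[:3] != grid.shape:
            raise ValueError("vectors do not match grid shape")
        if vectors.shape[-1] != len(feature_names):
            raise ValueError("vector length must equal len(feature_names)")
        self.grid = grid
        self.vectors = vectors
        self.feature_names = list(feature_names)

    @property
    def n_features(self) -> int:
        return len(self.feature_names)

    def as_matrix(self) -> np.ndarray:
        """Flattened (n_voxels, n_features) view for model fitting."""
        return self.vectors.reshape(-1, self.n_features)


def _sorted_eigvals_desc(mats: np.ndarray) -> np.ndarray:
    """Eigenvalues of symmetric 3×3 matrices, sorted descending by value."""
    return np.linalg.eigvalsh(mats)[..., ::-1]


def extract_channel_features(
    vol: IntensityVolume, scales: Sequence[float] = DEFAULT_SCALES_UM
) -> FeatureStack:
    """Compute the 8-feature family per scale for one channel.

    Scales smaller than half the coarsest voxel spacing are undersampled
    along that axis; a warning is emitted but the features are still
    computed.
    """
    scales = [float(s) for s in scales]
    if not scales or any(s <= 0 for s in scales):
        raise ValueError("scales must be a non-empty list of positive σ in μm")
    spacing = np.asarray(vol.grid.spacing, dtype=float)
    values = np.asarray(vol.values, dtype=np.float64)
    name = vol.channel_name or "ch"

    planes: list[np.ndarray] = []
    names: list[str] = []
    for sigma in scales:
        if sigma < max(spacing) / 2:
            warnings.warn(
                f"scale {sigma} μm is undersampled for spacing {tuple(spacing)}",
                stacklevel=2,
            )
        sig_vox = sigma / spacing

        smoothed = ndi.gaussian_filter(values, sig_vox, mode="nearest", truncate=_TRUNCATE)
        # First derivatives per μm via Gaussian derivative filters.
        grads = [
            ndi.gaussian_filter(values, sig_vox, order=tuple(int(a == i) for i in range(3)),
                                mode="nearest", truncate=_TRUNCATE) / spacing[a]
            for a in range(3)
        ]
        gradmag = np.sqrt(sum(g**2 for g in grads))

        hess = np.empty(values.shape + (3, 3))
        for a in range(3):
            for b in range(a, 3):
                order = tuple((a == i) + (b == i) for i in range(3))
                d2 = ndi.gaussian_filter(values, sig_vox, order=order, mode="nearest", truncate=_TRUNCATE)
                d2 /= spacing[a] * spacing[b]
                hess[..., a, b] = d2
                hess[..., b, a] = d2
        hess_eigs = _sorted_eigvals_desc(hess)
        del hess

        st = np.empty(values.shape + (3, 3))
        for a in range(3):
            for b in range(a, 3):
                comp = ndi.gaussian_filter(grads[a] * grads[b], sig_vox, mode="nearest", truncate=_TRUNCATE)
                st[..., a, b] = comp
                st[..., b, a] = comp
        st_eigs = _sorted_eigvals_desc(st)
        del st

        planes.extend(
            [smoothed, gradmag]
            + [hess_eigs[..., k] for k in range(3)]
            + [st_eigs[..., k] for k in range(3)]
        )
        names.extend(f"{name}:{fam}:s{sigma:g}" for fam in _FAMILIES)

    vectors = np.stack(planes, axis=-1).astype(np.float32)
    return FeatureStack(vol.grid, vectors, names)


def build_mfv(stacks: Sequence[FeatureStack]) -> FeatureStack:
    """Concatenate per-channel stacks into one multi-channel feature vector.

    Channel order is preserved in both the vectors and the names; no
    normalisation is applied (the downstream forests are scale-tolerant).
    """
    if not stacks:
        raise ValueError("at least one feature stack required")
    grid = stacks[0].grid
    for s in stacks[1:]:
        if s.grid != grid:
            raise ValueError("all feature stacks must share one grid")
    if len(stacks) == 1:
        return stacks[0]
    vectors = np.concatenate([s.vectors for s in stacks], axis=-1)
    names = [n for s in stacks for n in s.feature_names]
    return FeatureStack(grid, vectors, names)
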