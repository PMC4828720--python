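"""Random-forest voxel classification and structural cluster identification.

One binary forest per foreground class (tumor / astrocyte / proliferating /
vessel): each decides, from the multi-channel feature vector, whether a
voxel belongs to its class or to background. Positive predictions from
different classes may overlap — the classes are independent stains.
Forests default to 200 trees with 2 candidate features considered at each
split. Voxel masks are promoted to structural tumor clusters by connected
components with a physical-volume threshold; any component containing
epithelial (K8) signal is kept regardless of its size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.ensemble import RandomForestClassifier

from .core import BinaryMask, LabelVolume, connected_components, voxel_volume
from .features import FeatureStack

__all__ = [
    "ForestConfig",
    "TrainingLabels",
    "VoxelClassifier",
    "TumorCluster",
    "train_voxel_classifier",
    "classify_voxels",
    "cross_validate_f1",
    "segment_structures",
    "component_volume_histogram",
]


@dataclass(frozen=True)
class ForestConfig:
    """Random-forest hyperparameters (defaults: 200 trees, 2 candidate
    features per node)."""

    n_trees: int = 200
    candidate_features_per_node: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be positive")
        if self.candidate_features_per_node < 1:
            raise ValueError("candidate_features_per_node must be positive")


@dataclass
class TrainingLabels:
    """Sparse expert voxel annotations for one class.

    ``coords`` is an (N, 3) integer array of voxel indices; ``is_foreground``
    the corresponding boolean labels. Both classes must be represented.
    """

    coords: np.ndarray
    is_foreground: np.ndarray

    def __post_init__(self) -> None:
        self.coords = np.atleast_2d(np.asarray(self.coords, dtype=np.intp))
        self.is_foreground = np.asarray(self.is_foreground, dtype=bool).ravel()
        if self.coords.shape != (self.is_foreground.size, 3):
            raise ValueError("coords must be (N, 3) matching N labels")

    def validate_against(self, grid_shape: tuple[int, int, int]) -> None:
        if np.any(self.coords < 0) or np.any(self.coords >= np.asarray(grid_shape)):
            raise ValueError("label coordinates fall outside the grid")

    @property
    def n_foreground(self) -> int:
        return int(self.is_foreground.sum())

    @property
    def n_background(self) -> int:
        return int((~self.is_foreground).sum())


@dataclass
class VoxelClassifier:
    """A trained per-class binary forest plus the feature contract."""

    config: ForestConfig
    forest: RandomForestClassifier
    feature_names: list[str]
    target_class_name: str = ""


def _make_forest(config: ForestConfig, n_features: int) -> RandomForestClassifier:
    if config.candidate_features_per_node > n_features:
        raise ValueError(
            f"candidate_features_per_node={config.candidate_features_per_node} "
            f"exceeds feature count {n_features}"
        )
    return RandomForestClassifier(
        n_estimators=config.n_trees,
        max_features=config.candidate_features_per_node,
        random_state=config.seed,
        n_jobs=1,
    )


def _training_matrix(mfv: FeatureStack, labels: TrainingLabels):
    labels.validate_against(mfv.grid.shape)
    if labels.n_foreground == 0 or labels.n_background == 0:
        raise ValueError("training labels must contain both classes")
    x, y, z = labels.coords.T
    return mfv.vectors[x, y, z], labels.is_foreground


def train_voxel_classifier(
    mfv: FeatureStack,
    labels: TrainingLabels,
    config: ForestConfig = ForestConfig(),
    target_class_name: str = "",
) -> VoxelClassifier:
    """Fit a binary forest on the labeled voxels only; deterministic per seed."""
    X, y = _training_matrix(mfv, labels)
    forest = _make_forest(config, mfv.n_features).fit(X, y)
    return VoxelClassifier(config, forest, list(mfv.feature_names), target_class_name)


def classify_voxels(
    model: VoxelClassifier, mfv: FeatureStack, tile_voxels: int = 262_144
) -> BinaryMask:
    """Apply a trained classifier to every voxel.

    A voxel is foreground when the forest's majority vote (class-1
    probability) is ≥ 0.5. Prediction runs over flat tiles of
    ``tile_voxels`` voxels so memory stays bounded; tiling cannot change
    any prediction because voxels are classified independently.
    """
    if model.feature_names != mfv.feature_names:
        raise ValueError("feature names do not match the trained model")
    flat = mfv.as_matrix()
    out = np.empty(flat.shape[0], dtype=bool)
    pos = list(model.forest.classes_).index(True)
    for start in range(0, flat.shape[0], tile_voxels):
        tile = flat[start : start + tile_voxels]
        out[start : start + tile.shape[0]] = (
            model.forest.predict_proba(tile)[:, pos] >= 0.5
        )
    return BinaryMask(mfv.grid, out.reshape(mfv.grid.shape))


def _f1_from_counts(tp: int, fp: int, fn: int) -> float:
    denom = 2 * tp + fp + fn
    return 2 * tp / denom if denom else 0.0


def cross_validate_f1(
    mfv: FeatureStack,
    labels: TrainingLabels,
    config: ForestConfig = ForestConfig(),
    k: int = 10,
) -> float:
    """Stratified k-fold CV; F1 from the pooled out-of-fold confusion counts.

    F1 = 2·TP / (2·TP + FP + FN), the harmonic mean of precision and recall.
    """
    from sklearn.model_selection import StratifiedKFold

    if k < 2:
        raise ValueError("k must be >= 2")
    X, y = _training_matrix(mfv, labels)
    if labels.n_foreground < k or labels.n_background < k:
        raise ValueError(f"need at least k={k} labeled voxels per class")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=config.seed)
    tp = fp = fn = 0
    pred = np.empty_like(y)
    for train_idx, test_idx in skf.split(X, y):
        forest = _make_forest(config, X.shape[1]).fit(X[train_idx], y[train_idx])
        pred[test_idx] = forest.predict(X[test_idx])
    tp = int(np.sum(pred & y))
    fp = int(np.sum(pred & ~y))
    fn = int(np.sum(~pred & y))
    return _f1_from_counts(tp, fp, fn)


@dataclass
class TumorCluster:
    """One connected tumor component with its physical volume (μm³)."""

    id: int
    mask: BinaryMask
    volume_um3: float


def segment_structures(
    tumor_mask: BinaryMask,
    volume_threshold_um3: float,
    k8_mask: BinaryMask | None = None,
    connectivity: int = 26,
) -> list[TumorCluster]:
    """Promote a tumor voxel mask to structural clusters.

    Connected components with physical volume strictly above the threshold
    are kept; a component intersecting the K8 (epithelial) mask in at least
    one voxel is kept regardless of its size. Clusters are returned sorted
    by descending volume with stable ids 1..n (ties keep component scan
    order).
    """
    if volume_threshold_um3 < 0:
        raise ValueError("volume threshold must be >= 0")
    if k8_mask is not None and k8_mask.grid != tumor_mask.grid:
        raise ValueError("K8 mask must share the tumor mask's grid")
    labels = connected_components(tumor_mask, connectivity)
    n = labels.n_labels
    if n == 0:
        return []
    vv = voxel_volume(tumor_mask.grid)
    counts = np.bincount(labels.label.ravel(), minlength=n + 1)
    keep = counts[1:] * vv > volume_threshold_um3
    if k8_mask is not None and k8_mask.count:
        touched = np.unique(labels.label[k8_mask.member])
        keep[touched[touched > 0] - 1] = True
    kept = np.flatnonzero(keep) + 1
    order = kept[np.argsort(-counts[kept], kind="stable")]
    return [
        TumorCluster(
            id=i + 1,
            mask=BinaryMask(tumor_mask.grid, labels.label == lab),
            volume_um3=float(counts[lab] * vv),
        )
        for i, lab in enumerate(order)
    ]


def component_volume_histogram(
    tumor_mask: BinaryMask, connectivity: int = 26
) -> np.ndarray:
    """Sorted (descending) component volumes in μm³, to guide threshold choice.

    The structural volume threshold is an expert decision; this helper
    reports the full component-size spectrum so a user can place it.
    """
    labels = connected_components(tumor_mask, connectivity)
    if labels.n_labels == 0:
        return np.empty(0)
    counts = np.bincount(labels.label.ravel())[1:]
    return np.sort(counts)[::-1] * voxel_volume(tumor_mask.grid)
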