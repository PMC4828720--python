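"""Forest training/application, CV F1, structural segmentation."""

import numpy as np
import pytest
from sklearn.metrics import f1_score
from sklearn.model_selection import StratifiedKFold

from smart3d.classify import (
    ForestConfig,
    TrainingLabels,
    classify_voxels,
    cross_validate_f1,
    segment_structures,
    train_voxel_classifier,
)
from smart3d.core import BinaryMask, VoxelGrid, voxel_volume
from smart3d.features import FeatureStack


def _stack_from_values(values, extra=0):
    """A feature stack whose first feature is the given scalar volume."""
    values = np.asarray(values, float)
    grid = VoxelGrid(values.shape, (1, 1, 1))
    planes = [values] + [np.zeros(values.shape)] * extra
    names = [f"f{i}" for i in range(len(planes))]
    return FeatureStack(grid, np.stack(planes, -1), names)


def _separable_problem(rng, n_each=60):
    values = np.zeros((10, 10, 10))
    coords = np.argwhere(np.ones((10, 10, 10), bool))
    pick = rng.choice(len(coords), 2 * n_each, replace=False)
    fg, bg = coords[pick[:n_each]], coords[pick[n_each:]]
    values[tuple(fg.T)] = rng.uniform(5, 6, n_each)
    values[tuple(bg.T)] = rng.uniform(0, 1, n_each)
    labels = TrainingLabels(np.vstack([fg, bg]),
                            np.r_[np.ones(n_each, bool), np.zeros(n_each, bool)])
    return _stack_from_values(values, extra=1), labels


class TestTrainApply:
    def test_threshold_separable_data_memorised(self, rng):
        mfv, labels = _separable_problem(rng)
        model = train_voxel_classifier(mfv, labels, ForestConfig(seed=1), "tumor")
        mask = classify_voxels(model, mfv)
        assert np.all(mask.member[tuple(labels.coords[labels.is_foreground].T)])
        assert not np.any(mask.member[tuple(labels.coords[~labels.is_foreground].T)])

    def test_seeded_training_is_deterministic(self, rng):
        mfv, labels = _separable_problem(rng)
        cfg = ForestConfig(seed=42)
        m1 = train_voxel_classifier(mfv, labels, cfg)
        m2 = train_voxel_classifier(mfv, labels, cfg)
        assert np.array_equal(
            classify_voxels(m1, mfv).member, classify_voxels(m2, mfv).member
        )

    def test_tiled_and_untiled_application_identical(self, rng):
        mfv, labels = _separable_problem(rng)
        model = train_voxel_classifier(mfv, labels, ForestConfig(seed=0))
        full = classify_voxels(model, mfv, tile_voxels=10**9)
        tiled = classify_voxels(model, mfv, tile_voxels=97)
        assert np.array_equal(full.member, tiled.member)

    def test_single_class_labels_rejected(self, rng):
        mfv, labels = _separable_problem(rng)
        bad = TrainingLabels(labels.coords, np.ones(len(labels.coords), bool))
        with pytest.raises(ValueError):
            train_voxel_classifier(mfv, bad)

    def test_feature_name_mismatch_rejected(self, rng):
        mfv, labels = _separable_problem(rng)
        model = train_voxel_classifier(mfv, labels)
        other = FeatureStack(mfv.grid, mfv.vectors, ["a", "b"])
        with pytest.raises(ValueError):
            classify_voxels(model, other)

    def test_interleaved_gaussians_approach_bayes_f1(self, rng):
        # Two overlapping 1-D Gaussians: the Bayes rule thresholds at the
        # midpoint; its F1 is computable from the generating densities.
        from scipy.stats import norm

        n = 400
        mu0, mu1, sd = 0.0, 2.0, 1.0
        values = np.zeros((20, 20, 20))
        coords = np.argwhere(np.ones((20, 20, 20), bool))
        pick = rng.choice(len(coords), 2 * n, replace=False)
        fg, bg = coords[pick[:n]], coords[pick[n:]]
        values[tuple(fg.T)] = rng.normal(mu1, sd, n)
        values[tuple(bg.T)] = rng.normal(mu0, sd, n)
        values -= values.min()
        labels = TrainingLabels(np.vstack([fg, bg]),
                                np.r_[np.ones(n, bool), np.zeros(n, bool)])
        mfv = _stack_from_values(values, extra=1)
        f1 = cross_validate_f1(mfv, labels, ForestConfig(seed=3), k=5)
        thr = (mu0 + mu1) / 2
        recall = norm.sf(thr, mu1, sd)
        precision = recall / (recall + norm.sf(thr, mu0, sd))
        bayes_f1 = 2 * precision * recall / (precision + recall)
        assert abs(f1 - bayes_f1) < 0.05


class TestCrossValidatedF1:
    def test_perfectly_separable_gives_one(self, rng):
        mfv, labels = _separable_problem(rng)
        assert cross_validate_f1(mfv, labels, ForestConfig(seed=0), k=5) == 1.0

    def test_matches_pooled_confusion_oracle(self, rng):
        # noisy problem: recompute with an independent CV loop + sklearn F1
        values = rng.random((12, 12, 12))
        coords = np.argwhere(np.ones((12, 12, 12), bool))
        pick = rng.choice(len(coords), 160, replace=False)
        labs = rng.random(160) < 0.5
        values[tuple(coords[pick].T)] += np.where(labs, 0.35, 0.0)
        labels = TrainingLabels(coords[pick], labs)
        mfv = _stack_from_values(values, extra=1)
        cfg = ForestConfig(n_trees=50, seed=9)
        ours = cross_validate_f1(mfv, labels, cfg, k=4)
        X = mfv.vectors[tuple(coords[pick].T)]
        pred = np.empty(160, bool)
        for tr, te in StratifiedKFold(4, shuffle=True, random_state=9).split(X, labs):
            from sklearn.ensemble import RandomForestClassifier

            f = RandomForestClassifier(50, max_features=2, random_state=9, n_jobs=1)
            pred[te] = f.fit(X[tr], labs[tr]).predict(X[te])
        assert ours == pytest.approx(f1_score(labs, pred))

    def test_k_below_two_rejected(self, rng):
        mfv, labels = _separable_problem(rng)
        with pytest.raises(ValueError):
            cross_validate_f1(mfv, labels, k=1)

    def test_zero_true_positives_gives_zero_f1(self):
        from smart3d.classify import _f1_from_counts

        assert _f1_from_counts(0, 0, 25) == 0.0
        assert _f1_from_counts(0, 0, 0) == 0.0


class TestSegmentStructures:
    def _mask_with_components(self):
        member = np.zeros((20, 20, 20), bool)
        member[1:9, 1:9, 1:9] = True  # 512 voxels
        member[14:18, 14:18, 14:17] = True  # 48 voxels
        return BinaryMask(VoxelGrid((20, 20, 20), (1, 1, 1)), member)

    def test_volume_threshold_filters_small_components(self):
        mask = self._mask_with_components()
        clusters = segment_structures(mask, volume_threshold_um3=100.0)
        assert [c.volume_um3 for c in clusters] == [512.0]

    def test_k8_overlap_keeps_small_component_regardless_of_size(self):
        mask = self._mask_with_components()
        k8 = np.zeros((20, 20, 20), bool)
        k8[15, 15, 15] = True
        clusters = segment_structures(
            mask, 100.0, k8_mask=BinaryMask(mask.grid, k8)
        )
        assert len(clusters) == 2
        assert [c.id for c in clusters] == [1, 2]
        assert clusters[0].volume_um3 > clusters[1].volume_um3  # sorted desc

    def test_zero_threshold_keeps_every_component(self):
        mask = self._mask_with_components()
        assert len(segment_structures(mask, 0.0)) == 2

    def test_empty_input_gives_empty_list(self):
        grid = VoxelGrid((6, 6, 6), (1, 1, 1))
        assert segment_structures(BinaryMask(grid, np.zeros((6, 6, 6), bool)), 10) == []

    def test_cluster_volumes_use_physical_units(self):
        member = np.zeros((10, 10, 10), bool)
        member[2:4, 2:4, 2:4] = True
        mask = BinaryMask(VoxelGrid((10, 10, 10), (1.24, 1.24, 5.0)), member)
        (cluster,) = segment_structures(mask, 0.0)
        assert cluster.volume_um3 == pytest.approx(8 * voxel_volume(mask.grid))

    def test_sum_of_cluster_volumes_bounded_by_mask(self, rng):
        from conftest import random_mask

        mask = random_mask(rng, (14, 14, 14), density=0.2)
        clusters = segment_structures(mask, 0.0)
        assert sum(c.volume_um3 for c in clusters) == pytest.approx(mask.volume_um3)
        clusters = segment_structures(mask, 5.0)
        assert sum(c.volume_um3 for c in clusters) <= mask.volume_um3
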