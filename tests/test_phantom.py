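"""Synthetic scene generator: determinism, truth consistency, rendering."""

import numpy as np
import pytest

from smart3d.classify import TumorCluster
from smart3d.core import BinaryMask, IntensityVolume, VoxelGrid, voxel_volume
from smart3d.phantom import (
    BackgroundBlob,
    PhantomSpec,
    background_field,
    corrupt,
    generate_phantom,
    render_tube,
    render_vessel_tree,
    sample_training_labels,
)
from smart3d.quantify import gliosis_index, proliferation_ratio


def _small_spec(**kw):
    defaults = dict(
        grid=VoxelGrid((48, 48, 48), (1, 1, 1)),
        n_tumors=1,
        tumor_radius_range_um=(7.0, 9.0),
        n_vessels=2,
        n_nuclei=30,
        seed=5,
    )
    defaults.update(kw)
    return PhantomSpec(**defaults)


class TestGeneratePhantom:
    def test_empty_scene_is_pure_background(self):
        spec = _small_spec(
            n_tumors=0, n_vessels=0, n_nuclei=0,
            noise_gaussian_sigma=0.0, noise_poisson_scale=0.0,
            background_blobs=[BackgroundBlob((24, 24, 24), 20.0, 15.0)],
        )
        mcv, truth = generate_phantom(spec)
        bg = background_field(spec.grid, spec.background_blobs)
        for chan in mcv.channels:
            assert np.allclose(chan.values, bg, atol=1e-9)
        for mask in truth.masks.values():
            assert mask.count == 0

    def test_requested_tumor_count_realised(self):
        spec = _small_spec(grid=VoxelGrid((64, 64, 64), (1, 1, 1)), n_tumors=2, seed=2)
        _, truth = generate_phantom(spec)
        from smart3d.core import connected_components

        assert connected_components(truth.masks["tumor"]).n_labels == 2
        assert len(truth.tumor_records) == 2

    def test_deterministic_for_fixed_seed(self):
        a_mcv, a_truth = generate_phantom(_small_spec())
        b_mcv, b_truth = generate_phantom(_small_spec())
        for ca, cb in zip(a_mcv.channels, b_mcv.channels):
            assert np.array_equal(ca.values, cb.values)
        for name in a_truth.masks:
            assert np.array_equal(a_truth.masks[name].member, b_truth.masks[name].member)

    def test_truth_records_recomputable_from_masks(self):
        spec = _small_spec()
        _, truth = generate_phantom(spec)
        vv = voxel_volume(spec.grid)
        for rec in truth.tumor_records:
            member = truth.tumor_labels == rec.tumor_id
            cluster = TumorCluster(rec.tumor_id, BinaryMask(spec.grid, member),
                                   member.sum() * vv)
            assert cluster.volume_um3 == pytest.approx(rec.volume_um3, abs=1e-9)
            assert proliferation_ratio(cluster, truth.masks["proliferating"]) == (
                pytest.approx(rec.proliferative_index, abs=1e-9)
            )
            assert gliosis_index(
                cluster, truth.masks["astrocyte"], spec.astro_shell_um
            ) == pytest.approx(rec.gliosis_index, abs=1e-9)

    def test_targets_hit_within_placement_tolerance(self):
        _, truth = generate_phantom(_small_spec(seed=9))
        for rec in truth.tumor_records:
            assert rec.proliferative_index == pytest.approx(0.15, abs=0.02)
            assert rec.gliosis_index == pytest.approx(0.40, abs=0.005)

    def test_zone_restricted_proliferation_profile(self):
        spec = _small_spec(
            tumor_radius_range_um=(10.0, 11.0),
            edu_index_profile=lambda depth: 0.3 if depth < 0.5 else 0.0,
            seed=4,
        )
        _, truth = generate_phantom(spec)
        from smart3d.quantify import concentric_zones, zone_profile

        rec = truth.tumor_records[0]
        member = truth.tumor_labels == rec.tumor_id
        cluster = TumorCluster(1, BinaryMask(spec.grid, member), 1.0)
        zones = concentric_zones(cluster, spec.edu_zone_um, "inward")
        prof = zone_profile(zones, truth.masks["proliferating"])
        assert prof[0] > 0.2
        assert all(p < 0.05 for p in prof[1:])

    def test_overcrowded_scene_rejected(self):
        spec = _small_spec(n_tumors=6, tumor_radius_range_um=(10.0, 12.0))
        with pytest.raises(RuntimeError, match="unplaceable"):
            generate_phantom(spec)


class TestVesselRendering:
    def test_axis_aligned_tube_sections_are_discrete_disks(self):
        grid = VoxelGrid((11, 11, 30), (1, 1, 1))
        tube = render_tube(grid, (5.0, 5.0, 2.0), (0, 0, 1), 25.0, 2.0)
        yy, xx = np.meshgrid(np.arange(11), np.arange(11), indexing="ij")
        disk = (xx - 5) ** 2 + (yy - 5) ** 2 <= 4 + 1e-9
        for z in range(5, 25):
            assert np.array_equal(tube.member[:, :, z], disk)

    def test_same_seed_same_mask_and_walks_are_connected(self):
        spec = _small_spec(n_vessels=1, seed=13)
        m1 = render_vessel_tree(spec)
        m2 = render_vessel_tree(spec)
        assert np.array_equal(m1.member, m2.member)
        from smart3d.core import connected_components

        assert connected_components(m1).n_labels == 1

    def test_zero_tortuosity_gives_straight_centerline(self):
        spec = _small_spec(n_vessels=1, vessel_tortuosity=0.0, seed=1)
        from smart3d.phantom import _walk_centerline

        pts = _walk_centerline(spec, np.random.default_rng(1))
        d = np.diff(pts, axis=0)
        d = d / np.linalg.norm(d, axis=1, keepdims=True)
        assert np.allclose(d, d[0], atol=1e-9)


class TestCorrupt:
    def _flat(self, c=50.0):
        grid = VoxelGrid((40, 40, 40), (1, 1, 1))
        return IntensityVolume(grid, np.full(grid.shape, c), "ch")

    def test_zero_noise_zero_background_is_identity(self):
        spec = _small_spec(noise_gaussian_sigma=0, noise_poisson_scale=0,
                           background_blobs=[])
        vol = self._flat()
        out = corrupt(vol, spec)
        assert np.array_equal(out.values, vol.values)

    def test_single_blob_adds_analytic_gaussian(self):
        blob = BackgroundBlob((20, 20, 20), 30.0, 10.0)
        spec = _small_spec(noise_gaussian_sigma=0, noise_poisson_scale=0,
                           background_blobs=[blob])
        vol = self._flat()
        out = corrupt(vol, spec)
        coords = np.stack(np.meshgrid(*[np.arange(40.0)] * 3, indexing="ij"), -1)
        expected = 30.0 * np.exp(-((coords - 20.0) ** 2).sum(-1) / (2 * 100.0))
        assert np.allclose(out.values - vol.values, expected, atol=1e-9)

    def test_noise_moments_match_generating_parameters(self):
        sigma, scale, c = 4.0, 2.0, 50.0
        spec = _small_spec(noise_gaussian_sigma=sigma, noise_poisson_scale=scale,
                           background_blobs=[], seed=21)
        out = corrupt(self._flat(c), spec)
        var = out.values.var()
        expected = sigma**2 + scale * c  # Pois(c/s)·s has variance s·c
        assert abs(var - expected) / expected < 0.1


class TestTrainingLabelSampling:
    def test_stratified_counts_and_classes(self, rng):
        grid = VoxelGrid((20, 20, 20), (1, 1, 1))
        member = np.zeros(grid.shape, bool)
        member[5:12, 5:12, 5:12] = True
        labels = sample_training_labels(BinaryMask(grid, member), 0.05, rng)
        assert labels.n_foreground > 0 and labels.n_background > 0
        assert len(labels.coords) == int(round(0.05 * grid.n_voxels))
        member_at = member[tuple(labels.coords.T)]
        assert np.array_equal(member_at, labels.is_foreground)

    def test_invalid_fraction_rejected(self, rng):
        grid = VoxelGrid((8, 8, 8), (1, 1, 1))
        mask = BinaryMask(grid, np.ones(grid.shape, bool))
        with pytest.raises(ValueError):
            sample_training_labels(mask, 0.0, rng)
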