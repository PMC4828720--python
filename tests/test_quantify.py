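"""Spatial quantification: shells, zones, distances, densities."""

import numpy as np
import pytest

from smart3d.classify import TumorCluster
from smart3d.core import BinaryMask, EmptyMaskError, VoxelGrid, voxel_volume
from smart3d.quantify import (
    concentric_zones,
    gliosis_index,
    mean_vascular_density,
    proliferation_ratio,
    surrounding_space,
    tumor_to_vessel_distances,
    zone_profile,
)

from conftest import brute_force_distance_field


def _sphere_cluster(radius_um, shape=(56, 56, 56), spacing=(1, 1, 1), cid=1):
    grid = VoxelGrid(shape, spacing)
    coords = np.stack(
        np.meshgrid(*[np.arange(n) * s for n, s in zip(shape, spacing)], indexing="ij"), -1
    )
    center = (np.asarray(shape) - 1) * np.asarray(spacing) / 2
    member = ((coords - center) ** 2).sum(-1) <= radius_um**2
    mask = BinaryMask(grid, member)
    return TumorCluster(cid, mask, mask.count * voxel_volume(grid))


def _mask_like(cluster, member):
    return BinaryMask(cluster.mask.grid, member)


class TestProliferationRatio:
    def test_forced_ratios(self, rng):
        cluster = _sphere_cluster(8.0, (24, 24, 24))
        n = cluster.mask.count
        inside = np.argwhere(cluster.mask.member)
        edu = np.zeros(cluster.mask.grid.shape, bool)
        k = int(0.15 * n)
        edu[tuple(inside[rng.choice(n, k, replace=False)].T)] = True
        assert proliferation_ratio(cluster, _mask_like(cluster, edu)) == pytest.approx(k / n)

    def test_no_edu_inside_gives_zero_and_superset_gives_one(self):
        cluster = _sphere_cluster(6.0, (20, 20, 20))
        empty = _mask_like(cluster, np.zeros(cluster.mask.grid.shape, bool))
        assert proliferation_ratio(cluster, empty) == 0.0
        everything = _mask_like(cluster, np.ones(cluster.mask.grid.shape, bool))
        assert proliferation_ratio(cluster, everything) == 1.0

    def test_edu_outside_cluster_ignored(self):
        cluster = _sphere_cluster(5.0, (20, 20, 20))
        outside = _mask_like(cluster, ~cluster.mask.member)
        assert proliferation_ratio(cluster, outside) == 0.0


class TestSurroundingSpace:
    def test_zero_distance_gives_empty_shell(self):
        cluster = _sphere_cluster(6.0, (20, 20, 20))
        assert surrounding_space(cluster, 0.0).count == 0

    def test_shell_disjoint_from_cluster_and_matches_band_oracle(self):
        cluster = _sphere_cluster(10.0, (32, 32, 32))
        shell = surrounding_space(cluster, 3.0)
        assert not np.any(shell.member & cluster.mask.member)
        d = brute_force_distance_field(cluster.mask)
        oracle = (d > 0) & (d <= 3.0 + 1e-9)
        assert np.array_equal(shell.member, oracle)

    def test_gliosis_index_saturation_and_fraction(self, rng):
        cluster = _sphere_cluster(8.0, (40, 40, 40))
        shell = surrounding_space(cluster, 24.0)
        empty = _mask_like(cluster, np.zeros(cluster.mask.grid.shape, bool))
        assert gliosis_index(cluster, empty) == 0.0
        assert gliosis_index(cluster, shell) == 1.0
        idx = np.argwhere(shell.member)
        k = int(round(0.4 * shell.count))
        astro = np.zeros(cluster.mask.grid.shape, bool)
        astro[tuple(idx[rng.choice(len(idx), k, replace=False)].T)] = True
        assert gliosis_index(cluster, _mask_like(cluster, astro)) == pytest.approx(
            k / shell.count, abs=0.01
        )


class TestConcentricZones:
    def test_sphere_yields_expected_band_counts(self):
        cluster = _sphere_cluster(25.0)
        zones = concentric_zones(cluster, 10.0, "inward")
        assert zones.n_zones == 3
        # oracle: exhaustive distance-to-complement binning
        comp = BinaryMask(cluster.mask.grid, ~cluster.mask.member)
        depth = brute_force_distance_field(comp)
        for i, zone in enumerate(zones.zones):
            oracle = (
                cluster.mask.member
                & (depth > i * 10.0 + 1e-9)
                & (depth <= (i + 1) * 10.0 + 1e-9)
            )
            assert np.array_equal(zone.member, oracle)

    def test_inward_zones_partition_cluster(self):
        cluster = _sphere_cluster(17.0, (48, 48, 48), spacing=(1, 1, 2))
        zones = concentric_zones(cluster, 10.0, "inward")
        union = np.zeros(cluster.mask.grid.shape, bool)
        for zone in zones.zones:
            assert not np.any(union & zone.member)  # pairwise disjoint
            union |= zone.member
        assert np.array_equal(union, cluster.mask.member)

    def test_thin_cluster_gives_single_zone_equal_to_cluster(self):
        cluster = _sphere_cluster(4.0, (16, 16, 16))
        zones = concentric_zones(cluster, 10.0, "inward")
        assert zones.n_zones == 1
        assert np.array_equal(zones.zones[0].member, cluster.mask.member)

    def test_outward_requires_extent_and_excludes_cluster(self):
        cluster = _sphere_cluster(6.0, (40, 40, 40))
        with pytest.raises(ValueError):
            concentric_zones(cluster, 10.0, "outward")
        zones = concentric_zones(cluster, 10.0, "outward", max_extent_um=30.0)
        assert zones.n_zones == 3
        for zone in zones.zones:
            assert not np.any(zone.member & cluster.mask.member)


class TestZoneProfile:
    def test_empty_feature_gives_zeros_and_self_gives_ones(self):
        cluster = _sphere_cluster(15.0, (40, 40, 40))
        zones = concentric_zones(cluster, 5.0, "inward")
        empty = _mask_like(cluster, np.zeros(cluster.mask.grid.shape, bool))
        assert zone_profile(zones, empty) == [0.0] * zones.n_zones
        assert zone_profile(zones, cluster.mask) == [1.0] * zones.n_zones

    def test_empty_zone_flagged_as_nan(self):
        cluster = _sphere_cluster(6.0, (40, 40, 40))
        zones = concentric_zones(cluster, 10.0, "outward", max_extent_um=40.0)
        prof = zone_profile(zones, cluster.mask)
        # outermost band exceeds the grid: empty, hence nan not 0
        assert np.isnan(prof[-1])

    def test_conservation_and_zone_weighted_mean(self, rng):
        cluster = _sphere_cluster(16.0, (44, 44, 44))
        zones = concentric_zones(cluster, 7.0, "inward")
        feature = _mask_like(
            cluster, rng.random(cluster.mask.grid.shape) < 0.3
        )
        prof = zone_profile(zones, feature)
        counts = [z.count for z in zones.zones]
        recovered = sum(round(p * c) for p, c in zip(prof, counts) if c)
        assert recovered == int(np.count_nonzero(feature.member & cluster.mask.member))
        weighted = sum(p * c for p, c in zip(prof, counts)) / sum(counts)
        assert weighted == pytest.approx(proliferation_ratio(cluster, feature))


class TestVesselDistances:
    def test_pythagorean_offset(self):
        grid = VoxelGrid((10, 10, 10), (1, 1, 1))
        vessel = np.zeros((10, 10, 10), bool)
        vessel[1, 1, 1] = True
        tumor = np.zeros((10, 10, 10), bool)
        tumor[4, 5, 1] = True  # offset (3, 4, 0)
        cluster = TumorCluster(1, BinaryMask(grid, tumor), 1.0)
        dists, _ = tumor_to_vessel_distances(cluster, BinaryMask(grid, vessel))
        assert dists[0] == pytest.approx(5.0)

    def test_zero_distance_on_vessel_and_empty_vessel_rejected(self):
        cluster = _sphere_cluster(4.0, (16, 16, 16))
        dists, mode = tumor_to_vessel_distances(cluster, cluster.mask)
        assert np.all(dists == 0) and mode == 0.0
        empty = _mask_like(cluster, np.zeros(cluster.mask.grid.shape, bool))
        with pytest.raises(EmptyMaskError):
            tumor_to_vessel_distances(cluster, empty)

    @pytest.mark.parametrize("spacing", [(1, 1, 1), (1.24, 1.24, 5.0)])
    def test_matches_all_pairs_oracle(self, rng, spacing):
        grid = VoxelGrid((14, 14, 14), spacing)
        vessel = BinaryMask(grid, rng.random(grid.shape) < 0.02)
        if vessel.count == 0:
            vessel.member[3, 3, 3] = True
        tumor = BinaryMask(grid, rng.random(grid.shape) < 0.1)
        cluster = TumorCluster(1, tumor, tumor.count * voxel_volume(grid))
        dists, _ = tumor_to_vessel_distances(cluster, vessel)
        oracle = brute_force_distance_field(vessel)[tumor.member]
        assert np.abs(np.sort(dists) - np.sort(oracle)).max() < 1e-6

    def test_distances_invariant_under_axis_permutation(self, rng):
        grid = VoxelGrid((12, 12, 12), (1.0, 2.0, 0.5))
        vessel = rng.random(grid.shape) < 0.05
        tumor = rng.random(grid.shape) < 0.1
        cluster = TumorCluster(1, BinaryMask(grid, tumor), 1.0)
        d1, _ = tumor_to_vessel_distances(cluster, BinaryMask(grid, vessel))
        perm = (2, 0, 1)
        grid_p = VoxelGrid(tuple(np.array(grid.shape)[list(perm)]),
                           tuple(np.array(grid.spacing)[list(perm)]))
        cluster_p = TumorCluster(1, BinaryMask(grid_p, tumor.transpose(perm)), 1.0)
        d2, _ = tumor_to_vessel_distances(cluster_p, BinaryMask(grid_p, vessel.transpose(perm)))
        assert np.allclose(np.sort(d1), np.sort(d2))


class TestVascularDensity:
    def test_saturation_cases(self):
        cluster = _sphere_cluster(6.0, (40, 40, 40))
        shell = surrounding_space(cluster, 10.0)
        intra, peri = mean_vascular_density(cluster, shell, 10.0)
        assert (intra, peri) == (0.0, 1.0)
        none = _mask_like(cluster, np.zeros(cluster.mask.grid.shape, bool))
        assert mean_vascular_density(cluster, none, 10.0) == (0.0, 0.0)

    def test_designed_intratumoral_fraction_recovered(self, rng):
        cluster = _sphere_cluster(12.0, (40, 40, 40))
        inside = np.argwhere(cluster.mask.member)
        vessel = np.zeros(cluster.mask.grid.shape, bool)
        k = int(round(0.02 * cluster.mask.count))
        vessel[tuple(inside[rng.choice(len(inside), k, replace=False)].T)] = True
        intra, _ = mean_vascular_density(cluster, _mask_like(cluster, vessel), 10.0)
        assert intra == pytest.approx(0.02, abs=0.005)
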