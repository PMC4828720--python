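"""End-to-end validation experiments on synthetic phantoms.

Each function runs one self-contained experiment — oracle equivalence of
the geometric primitives, zone-conservation checks, classifier sanity on a
four-class scene, background-removal recovery, end-to-end parameter
recovery, statistical calibration, and slice-alignment recovery — and
returns the measured quantities as a flat dict. The brute-force reference
computations here (all-pairs / tree-based nearest neighbours, per-voxel
window percentiles) are deliberately independent of the implementation
paths they check.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage as ndi
from scipy.spatial import cKDTree
from scipy.stats import kstest

from .background import WindowSpec, remove_background
from .classify import ForestConfig, TumorCluster, cross_validate_f1, segment_structures
from .core import BinaryMask, IntensityVolume, VoxelGrid, dilate_by_distance, distance_transform
from .features import DEFAULT_SCALES_UM
from .io import align_slices
from .phantom import (
    BackgroundBlob,
    PhantomSpec,
    background_field,
    corrupt,
    generate_phantom,
    render_vessel_tree,
    sample_training_labels,
)
from .pipeline import (
    PipelineParams,
    classify_all,
    extract_mfv,
    preprocess,
    train_classifiers,
)
from .quantify import (
    concentric_zones,
    gliosis_index,
    proliferation_ratio,
    surrounding_space,
    tumor_to_vessel_distances,
    zone_profile,
)
from .stats import gaussian_kde, quadratic_fit, variance_f_test

PHANTOM_CLASSES = ("tumor", "astrocyte", "proliferating", "vessel")


def _reference_distance_field(mask: BinaryMask) -> np.ndarray:
    """Nearest-neighbour distances by direct search (all-pairs or k-d tree)."""
    spacing = np.asarray(mask.grid.spacing)
    pts = np.argwhere(mask.member) * spacing
    coords = np.argwhere(np.ones(mask.grid.shape, bool)) * spacing
    if len(pts) * len(coords) <= 2e7:
        out = np.sqrt(((coords[:, None, :] - pts[None]) ** 2).sum(-1).min(1))
    else:
        out, _ = cKDTree(pts).query(coords, k=1)
    return out.reshape(mask.grid.shape)


def _random_mask(rng, max_edge=20, density=0.05):
    shape = tuple(int(rng.integers(6, max_edge + 1)) for _ in range(3))
    spacing = tuple(rng.choice([0.5, 1.0, 1.24, 2.0, 5.0], 3))
    member = rng.random(shape) < density
    if not member.any():
        member[tuple(rng.integers(0, n) for n in shape)] = True
    return BinaryMask(VoxelGrid(shape, spacing), member)


def _random_blob_cluster(rng, shape=(26, 26, 26)):
    grid = VoxelGrid(shape, (1.0, 1.0, 1.0))
    member = np.zeros(shape, bool)
    coords = np.stack(np.meshgrid(*[np.arange(float(n)) for n in shape], indexing="ij"), -1)
    for _ in range(int(rng.integers(1, 4))):
        c = rng.uniform(6, np.asarray(shape) - 6)
        r = rng.uniform(3, 7)
        member |= ((coords - c) ** 2).sum(-1) <= r**2
    lab, n = ndi.label(member)
    if n > 1:  # keep the largest component: clusters are connected
        counts = np.bincount(lab.ravel())[1:]
        member = lab == (1 + int(np.argmax(counts)))
    mask = BinaryMask(grid, member)
    return TumorCluster(1, mask, float(mask.count))


def oracle_equivalence(seed: int, n_instances: int = 50) -> dict:
    """Geometric primitives vs exhaustive references on random instances."""
    rng = np.random.default_rng(seed)
    dist_err = dil_mismatch = perc_err = zone_mismatch = vessel_err = 0.0

    for _ in range(n_instances):
        mask = _random_mask(rng)
        ref = _reference_distance_field(mask)
        dist_err = max(dist_err, float(np.abs(distance_transform(mask) - ref).max()))

        radius = float(rng.uniform(0, 6))
        dil = dilate_by_distance(mask, radius)
        dil_ref = ref <= radius + 1e-9
        dil_mismatch = max(dil_mismatch, float(np.sum(dil.member != dil_ref)))

    for _ in range(n_instances):
        shape = tuple(int(rng.integers(6, 13)) for _ in range(3))
        values = rng.random(shape) * 100
        edge = int(rng.choice([3, 5]))
        if edge > min(shape):
            edge = 3
        pct = float(rng.uniform(5, 95))
        vol = IntensityVolume(VoxelGrid(shape, (1, 1, 1)), values)
        from .background import estimate_rough_background

        rough = estimate_rough_background(vol, WindowSpec(edge, pct))
        h = edge // 2
        ref = np.empty(shape)
        for x in range(shape[0]):
            for y in range(shape[1]):
                for z in range(shape[2]):
                    w = values[
                        max(x - h, 0) : x + h + 1,
                        max(y - h, 0) : y + h + 1,
                        max(z - h, 0) : z + h + 1,
                    ]
                    ref[x, y, z] = np.percentile(w, pct)
        perc_err = max(perc_err, float(np.abs(rough.values - ref).max()))

    for _ in range(n_instances):
        cluster = _random_blob_cluster(rng)
        thickness = float(rng.uniform(2, 8))
        zones = concentric_zones(cluster, thickness, "inward")
        comp = BinaryMask(cluster.mask.grid, ~cluster.mask.member)
        depth = _reference_distance_field(comp)
        for i, zone in enumerate(zones.zones):
            ref = (
                cluster.mask.member
                & (depth > i * thickness + 1e-9)
                & (depth <= (i + 1) * thickness + 1e-9)
            )
            zone_mismatch = max(zone_mismatch, float(np.sum(zone.member != ref)))

    for _ in range(n_instances):
        mask = _random_mask(rng, max_edge=16, density=0.1)
        vessel = BinaryMask(mask.grid, rng.random(mask.grid.shape) < 0.03)
        if vessel.count == 0:
            vessel.member[0, 0, 0] = True
        cluster = TumorCluster(1, mask, float(mask.count))
        dists, _ = tumor_to_vessel_distances(cluster, vessel)
        ref = _reference_distance_field(vessel)[mask.member]
        vessel_err = max(vessel_err, float(np.abs(np.sort(dists) - np.sort(ref)).max()))

    return {
        "distance_transform_max_abs_error_um": dist_err,
        "dilation_mismatch_voxels": dil_mismatch,
        "window_percentile_max_abs_error": perc_err,
        "zone_decomposition_mismatch_voxels": zone_mismatch,
        "tumor_vessel_distance_max_abs_error_um": vessel_err,
        "n_instances_per_operation": n_instances,
    }


def zone_conservation(seed: int) -> dict:
    """Zone profiles must conserve feature volume and partition the tumor."""
    spec = PhantomSpec(
        grid=VoxelGrid((48, 48, 48), (1.0, 1.0, 1.0)),
        n_tumors=1,
        tumor_radius_range_um=(8.0, 10.0),
        n_vessels=2,
        seed=seed,
    )
    _, truth = generate_phantom(spec)
    rng = np.random.default_rng(seed + 1)
    worst = 0
    partition_ok = True
    n_tumors = 0
    for rec in truth.tumor_records:
        member = truth.tumor_labels == rec.tumor_id
        cluster = TumorCluster(rec.tumor_id, BinaryMask(spec.grid, member), 1.0)
        zones = concentric_zones(cluster, 10.0, "inward")
        union = np.zeros(spec.grid.shape, bool)
        for zone in zones.zones:
            if np.any(union & zone.member):
                partition_ok = False
            union |= zone.member
        if not np.array_equal(union, member):
            partition_ok = False
        for feature in (
            truth.masks["proliferating"],
            BinaryMask(spec.grid, rng.random(spec.grid.shape) < 0.3),
        ):
            prof = zone_profile(zones, feature)
            counts = [z.count for z in zones.zones]
            recovered = sum(round(p * c) for p, c in zip(prof, counts) if c)
            exact = int(np.count_nonzero(feature.member & member))
            worst = max(worst, abs(recovered - exact))
        n_tumors += 1
    return {
        "zone_conservation_max_abs_error_voxels": worst,
        "inward_zones_partition_tumor": int(partition_ok),
        "n_tumors_checked": n_tumors,
    }


def _classifier_phantom(seed: int):
    return PhantomSpec(
        grid=VoxelGrid((64, 64, 64), (1.0, 1.0, 1.0)),
        tumor_radius_range_um=(6.0, 9.0),
        seed=seed,
    )


def classifier_sanity(seed: int, label_fraction: float = 0.01) -> dict:
    """Four-class voxel classification on a seeded 64³ scene.

    Channels pass through background removal first — the classifier stage
    always operates downstream of it, and the smooth autofluorescence field
    otherwise lifts object halos across the decision boundary.
    """
    spec = _classifier_phantom(seed)
    mcv, truth = generate_phantom(spec)
    params = PipelineParams(forest=ForestConfig(seed=seed))
    mfv = extract_mfv(preprocess(mcv, params), params)
    rng = np.random.default_rng(seed)
    labels = {
        c: sample_training_labels(truth.masks[c], label_fraction, rng)
        for c in PHANTOM_CLASSES
    }
    models = train_classifiers(mfv, labels, params)
    masks = classify_all(models, mfv)
    out: dict = {"n_voxels": spec.grid.n_voxels}
    for c in PHANTOM_CLASSES:
        out[f"cv_f1_{c}"] = cross_validate_f1(mfv, labels[c], params.forest, k=10)
        err = (masks[c].count - truth.masks[c].count) / truth.masks[c].count
        out[f"volume_error_pct_{c}"] = 100.0 * err
    return out


def background_recovery(seed: int) -> dict:
    """Removal of a known smooth background under thin bright filaments."""
    grid = VoxelGrid((48, 48, 48), (1.0, 1.0, 1.0))
    rng = np.random.default_rng(seed)
    blobs = [
        BackgroundBlob(tuple(rng.uniform(5, 43, 3)), float(rng.uniform(25, 40)),
                       float(rng.uniform(14, 24)))
        for _ in range(3)
    ]
    spec = PhantomSpec(
        grid=grid,
        n_vessels=6,
        vessel_radius_um=1.0,
        vessel_tortuosity=0.2,
        noise_gaussian_sigma=2.0,
        noise_poisson_scale=1.0,
        background_blobs=blobs,
        seed=seed,
    )
    filaments = render_vessel_tree(spec)
    clean = ndi.gaussian_filter(filaments.member.astype(float) * spec.channel_amplitude, 1.0)
    vol = corrupt(IntensityVolume(grid, clean, "GFAP"), spec)
    out = remove_background(vol, WindowSpec(7, 20.0))
    bg_true = background_field(grid, blobs)
    net = np.clip(vol.values - bg_true, 0, None)
    bg_vox = ~filaments.member & (clean < 5)
    reduction = float(vol.values[bg_vox].mean() / max(out.values[bg_vox].mean(), 1e-9))
    retained = float(
        np.mean(out.values[filaments.member] >= 0.8 * net[filaments.member])
    )
    return {
        "background_residual_reduction_factor": reduction,
        "filament_net_intensity_retention_fraction": retained,
        "n_filament_voxels": int(filaments.count),
    }


def parameter_recovery(seed: int) -> dict:
    """Full pipeline on the default scene: recover volume, proliferative
    index (target 0.15) and gliosis index (target 0.40) per tumor."""
    spec = PhantomSpec(seed=seed)
    mcv, truth = generate_phantom(spec)
    params = PipelineParams(
        forest=ForestConfig(seed=seed),
        volume_threshold_um3=500.0,
        feature_scales_um=DEFAULT_SCALES_UM,
    )
    cleaned = preprocess(mcv, params)
    mfv = extract_mfv(cleaned, params)
    rng = np.random.default_rng(seed)
    labels = {
        c: sample_training_labels(truth.masks[c], 0.01, rng) for c in PHANTOM_CLASSES
    }
    models = train_classifiers(mfv, labels, params)
    masks = classify_all(models, mfv)
    clusters = segment_structures(masks["tumor"], params.volume_threshold_um3)

    prolif_err = gliosis_err = vol_err = -1.0
    matched = 0
    for cluster in clusters:
        overlap = truth.tumor_labels[cluster.mask.member]
        overlap = overlap[overlap > 0]
        if overlap.size == 0:
            continue
        rec = truth.tumor_records[int(np.bincount(overlap).argmax()) - 1]
        matched += 1
        prolif = proliferation_ratio(cluster, masks["proliferating"])
        gli = gliosis_index(cluster, masks["astrocyte"], spec.astro_shell_um)
        prolif_err = max(prolif_err, abs(prolif - spec.target_proliferative_index))
        gliosis_err = max(gliosis_err, abs(gli - spec.astro_shell_coverage))
        vol_err = max(vol_err, abs(cluster.volume_um3 - rec.volume_um3) / rec.volume_um3)
    return {
        "n_tumors_recovered": matched,
        "n_tumors_true": len(truth.tumor_records),
        "proliferative_index_max_abs_error": prolif_err,
        "gliosis_index_max_abs_error": gliosis_err,
        "tumor_volume_max_rel_error_pct": 100.0 * vol_err,
    }


def stats_calibration(seed: int, n_reps: int = 1000) -> dict:
    """Type-I error of the curvature test and the variance F-test under
    their nulls; KDE normalisation; F-test p-value uniformity."""
    rng = np.random.default_rng(seed)
    quad_hits = 0
    for _ in range(n_reps):
        x = rng.uniform(0, 1, 25)
        y = 1.0 + 2.0 * x + rng.normal(0, 0.1, 25)  # no curvature
        if quadratic_fit(x, y).p_value < 0.05:
            quad_hits += 1
    f_hits = 0
    pvals = np.empty(n_reps)
    for i in range(n_reps):
        a = rng.normal(0, 1, 20)
        b = rng.normal(0, 1, 20)  # equal variances
        pvals[i] = variance_f_test(a, b).p_value
        f_hits += pvals[i] < 0.05
    kde = gaussian_kde(rng.normal(0, 1, 200))
    grid = kde.grid(4096, pad_sigmas=8)
    integral = float(np.trapezoid(kde(grid), grid))
    return {
        "quadratic_type1_error_rate": quad_hits / n_reps,
        "f_test_type1_error_rate": f_hits / n_reps,
        "f_test_p_uniformity_ks_p": float(kstest(pvals, "uniform").pvalue),
        "kde_integral": integral,
        "n_null_replicates": n_reps,
    }


def alignment_recovery(seed: int, n_stacks: int = 100, max_shift: int = 5) -> dict:
    """Exact recovery of known integer plane shifts on seeded stacks."""
    rng = np.random.default_rng(seed)
    exact = 0
    for _ in range(n_stacks):
        base = ndi.gaussian_filter(rng.random((32, 32)) * 100, 1.0)
        nz = int(rng.integers(3, 7))
        truth = [(0, 0)] + [
            (int(rng.integers(-max_shift, max_shift + 1)),
             int(rng.integers(-max_shift, max_shift + 1)))
            for _ in range(nz - 1)
        ]
        planes, cur = [base], base
        for dx, dy in truth[1:]:
            nxt = np.zeros_like(cur)
            sx0, sx1 = max(0, -dx), min(32, 32 - dx)
            sy0, sy1 = max(0, -dy), min(32, 32 - dy)
            nxt[sx0 + dx : sx1 + dx, sy0 + dy : sy1 + dy] = cur[sx0:sx1, sy0:sy1]
            planes.append(nxt)
            cur = nxt
        stack = IntensityVolume(
            VoxelGrid((32, 32, nz), (1, 1, 1)), np.stack(planes, -1)
        )
        shifts, _ = align_slices(stack, max_shift)
        exact += shifts == truth
    return {
        "alignment_exact_recovery_rate": exact / n_stacks,
        "n_stacks": n_stacks,
        "max_shift_voxels": max_shift,
    }
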