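"""Synthetic 3D metastatic-landscape phantoms with ground truth.

Generates multi-channel volumes that emulate the structures seen in
tissue-cleared brain-metastasis imaging — lobular tumor clusters (unions of
overlapping spheres, optionally chained along a vessel to mimic vascular
co-option), tortuous tube-shaped vessels, partial astrocyte shells hugging
the tumor surface, proliferation (EdU) spots placed per concentric zone,
scattered nuclei, smooth sum-of-Gaussians autofluorescence background, and
mixed Poisson + Gaussian noise — so every pipeline stage can be exercised
and validated without any microscopy data.

Ground truth consists of the pre-noise per-class indicator masks plus
per-tumor records (volume, proliferative index, gliosis index) that are
recomputed from those masks, so stored truth and mask-derived truth agree
exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import ndimage as ndi

from .classify import TrainingLabels, TumorCluster
from .core import (
    BinaryMask,
    IntensityVolume,
    MultiChannelVolume,
    VoxelGrid,
    dilate_by_distance,
    voxel_volume,
)
from .quantify import concentric_zones, gliosis_index, proliferation_ratio, surrounding_space

__all__ = [
    "BackgroundBlob",
    "PhantomSpec",
    "TumorTruth",
    "GroundTruth",
    "generate_phantom",
    "render_vessel_tree",
    "render_tube",
    "corrupt",
    "background_field",
    "sample_training_labels",
]

CHANNEL_FOR_CLASS = {
    "tumor": "K8",
    "astrocyte": "GFAP",
    "proliferating": "EdU",
    "vessel": "vessel",
    "nuclei": "DAPI",
}


@dataclass(frozen=True)
class BackgroundBlob:
    """One Gaussian component of the smooth background field."""

    center_um: tuple[float, float, float]
    amplitude: float
    sigma_um: float


def _default_grid() -> VoxelGrid:
    return VoxelGrid((72, 72, 72), (1.0, 1.0, 1.0))


@dataclass
class PhantomSpec:
    """Scene parameters for one synthetic metastatic landscape.

    Defaults describe the canonical test scene: a 72³ voxel volume at 1 μm
    isotropic pitch holding two well-separated lobular tumors (radius
    9–12 μm, three lobes), three tortuous vessels of 3 μm radius, astrocyte
    caps covering 40% of each tumor's 24 μm shell, and EdU spots placed to
    a proliferative index of 0.15, over a sum-of-Gaussians background with
    mixed Poisson/Gaussian noise.
    """

    grid: VoxelGrid = field(default_factory=_default_grid)
    n_tumors: int = 2
    tumor_radius_range_um: tuple[float, float] = (9.0, 12.0)
    lobularity: int = 3
    vessel_cooption: bool = False
    n_vessels: int = 3
    vessel_radius_um: float = 3.0
    vessel_tortuosity: float = 0.3  # per-step direction jitter (radians-scale)
    astro_shell_coverage: float = 0.4
    astro_shell_um: float = 24.0
    astro_process_length_um: float = 6.0
    target_proliferative_index: float = 0.15
    edu_index_profile: Callable[[float], float] | None = None
    edu_spot_radius_um: float = 3.0  # S-phase nucleus radius
    edu_zone_um: float = 10.0
    n_nuclei: int = 120
    nucleus_radius_um: float = 3.0
    background_blobs: Sequence[BackgroundBlob] | None = None
    n_background_blobs: int = 4
    background_amplitude: float = 30.0
    background_sigma_um: float = 18.0
    noise_gaussian_sigma: float = 3.0
    noise_poisson_scale: float = 1.0
    channel_amplitude: float = 180.0
    psf_sigma_um: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_tumors < 0 or self.n_vessels < 0 or self.n_nuclei < 0:
            raise ValueError("counts must be >= 0")
        if not 0 <= self.astro_shell_coverage <= 1:
            raise ValueError("astro_shell_coverage must be in [0, 1]")
        lo, hi = self.tumor_radius_range_um
        if lo <= 0 or hi < lo:
            raise ValueError("tumor radius range must be positive and ordered")
        if self.vessel_radius_um <= 0 or self.edu_spot_radius_um <= 0:
            raise ValueError("radii must be positive")
        if self.noise_gaussian_sigma < 0 or self.noise_poisson_scale < 0:
            raise ValueError("noise parameters must be >= 0")


@dataclass
class TumorTruth:
    """Per-tumor true quantities, recomputable from the truth masks."""

    tumor_id: int
    volume_um3: float
    proliferative_index: float
    gliosis_index: float


@dataclass
class GroundTruth:
    """Pre-noise per-class masks and per-tumor records."""

    masks: dict[str, BinaryMask]
    tumor_records: list[TumorTruth]
    tumor_labels: np.ndarray  # per-voxel tumor id (0 = none)


def _phys_coords(grid: VoxelGrid) -> np.ndarray:
    """(nx, ny, nz, 3) array of voxel-centre positions in μm."""
    axes = [np.arange(n) * s for n, s in zip(grid.shape, grid.spacing)]
    return np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1)


def _ball_window(grid: VoxelGrid, center_um, reach_um):
    spacing = np.asarray(grid.spacing)
    lo = np.maximum(np.floor((np.asarray(center_um) - reach_um) / spacing), 0).astype(int)
    hi = np.minimum(
        np.ceil((np.asarray(center_um) + reach_um) / spacing) + 1, grid.shape
    ).astype(int)
    if np.any(lo >= hi):
        return None, None
    axes = [np.arange(lo[a], hi[a]) * spacing[a] - center_um[a] for a in range(3)]
    d2 = (
        axes[0][:, None, None] ** 2
        + axes[1][None, :, None] ** 2
        + axes[2][None, None, :] ** 2
    )
    return tuple(slice(lo[a], hi[a]) for a in range(3)), d2


def _paint_ball(mask: np.ndarray, grid: VoxelGrid, center_um, radius_um) -> None:
    """Digital ball: voxels whose centre lies within the analytic sphere."""
    sub, d2 = _ball_window(grid, center_um, radius_um)
    if sub is not None:
        mask[sub] |= d2 <= radius_um**2 + 1e-9


def _paint_ball_soft(arr: np.ndarray, grid: VoxelGrid, center_um, radius_um) -> None:
    """Partial-volume ball: coverage ramps linearly from 1 inside to 0
    outside across one voxel pitch, crossing 0.5 exactly at the analytic
    surface — so thresholding the soft scene at 0.5 reproduces the digital
    truth mask and the rendered half-intensity surface does not inflate
    small objects."""
    h = min(grid.spacing)
    sub, d2 = _ball_window(grid, center_um, radius_um + h)
    if sub is not None:
        cov = np.clip((radius_um + h / 2 - np.sqrt(d2)) / h, 0.0, 1.0)
        np.maximum(arr[sub], cov, out=arr[sub])


def render_tube(
    grid: VoxelGrid,
    start_um,
    direction,
    length_um: float,
    radius_um: float,
    step_um: float = 0.5,
) -> BinaryMask:
    """A straight tube: union of balls stamped along a line segment."""
    direction = np.asarray(direction, dtype=float)
    direction = direction / np.linalg.norm(direction)
    mask = np.zeros(grid.shape, dtype=bool)
    for t in np.arange(0.0, length_um + step_um / 2, step_um):
        _paint_ball(mask, grid, np.asarray(start_um) + t * direction, radius_um)
    return BinaryMask(grid, mask)


def _walk_centerline(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """A tortuous random-walk centerline entering from a random face."""
    extent = np.asarray(spec.grid.shape) * np.asarray(spec.grid.spacing)
    axis = int(rng.integers(3))
    side = int(rng.integers(2))
    start = rng.uniform(0.15, 0.85, 3) * extent
    start[axis] = 0.0 if side == 0 else extent[axis]
    direction = rng.normal(0, 0.2, 3)
    direction[axis] = 1.0 if side == 0 else -1.0
    direction /= np.linalg.norm(direction)
    step = 1.0
    pts = [start.copy()]
    pos = start.copy()
    for _ in range(int(3 * extent.sum())):
        if spec.vessel_tortuosity > 0:
            direction = direction + spec.vessel_tortuosity * rng.normal(0, step * 0.3, 3)
            direction /= np.linalg.norm(direction)
        pos = pos + step * direction
        if np.any(pos < -spec.vessel_radius_um) or np.any(
            pos > extent + spec.vessel_radius_um
        ):
            break
        pts.append(pos.copy())
    return np.asarray(pts)


def render_vessel_tree(
    spec: PhantomSpec, rng: np.random.Generator | None = None
) -> BinaryMask:
    """Union of tubes around seeded tortuous random-walk centerlines."""
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    mask = np.zeros(spec.grid.shape, dtype=bool)
    for _ in range(spec.n_vessels):
        pts = _walk_centerline(spec, rng)
        dense = []
        for a, b in zip(pts[:-1], pts[1:]):
            seg = np.linalg.norm(b - a)
            for t in np.arange(0.0, seg, 0.5):
                dense.append(a + t / seg * (b - a))
        dense.append(pts[-1])
        for p in dense:
            _paint_ball(mask, spec.grid, p, spec.vessel_radius_um)
    return BinaryMask(spec.grid, mask)


def background_field(grid: VoxelGrid, blobs: Sequence[BackgroundBlob]) -> np.ndarray:
    """Sum-of-Gaussians smooth background evaluated at voxel centres."""
    out = np.zeros(grid.shape)
    coords = _phys_coords(grid)
    for blob in blobs:
        d2 = ((coords - np.asarray(blob.center_um)) ** 2).sum(-1)
        out += blob.amplitude * np.exp(-d2 / (2 * blob.sigma_um**2))
    return out


def _resolve_blobs(spec: PhantomSpec, rng: np.random.Generator) -> list[BackgroundBlob]:
    if spec.background_blobs is not None:
        return list(spec.background_blobs)
    extent = np.asarray(spec.grid.shape) * np.asarray(spec.grid.spacing)
    return [
        BackgroundBlob(
            tuple(rng.uniform(0, 1, 3) * extent),
            spec.background_amplitude * rng.uniform(0.5, 1.0),
            spec.background_sigma_um * rng.uniform(0.7, 1.3),
        )
        for _ in range(spec.n_background_blobs)
    ]


def corrupt(
    vol: IntensityVolume,
    spec: PhantomSpec,
    rng: np.random.Generator | None = None,
    blobs: Sequence[BackgroundBlob] | None = None,
) -> IntensityVolume:
    """Add the smooth background then apply Poisson-scaled + Gaussian noise.

    The Poisson stage draws ``Pois(v / s) · s`` (signal-dependent shot
    noise, variance ≈ s·v); the Gaussian stage adds read-out noise of
    standard deviation ``noise_gaussian_sigma``. Output is clipped at 0.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    if blobs is None:
        blobs = _resolve_blobs(spec, rng)
    values = vol.values + (background_field(vol.grid, blobs) if blobs else 0.0)
    if spec.noise_poisson_scale > 0:
        values = rng.poisson(values / spec.noise_poisson_scale) * spec.noise_poisson_scale
    values = np.asarray(values, dtype=float)
    if spec.noise_gaussian_sigma > 0:
        values = values + rng.normal(0, spec.noise_gaussian_sigma, values.shape)
    return IntensityVolume(vol.grid, np.clip(values, 0, None), vol.channel_name)


def _place_tumors(spec, rng, vessel_pts):
    """Sample tumor centres/radii so that no tumor intrudes into another's
    gliosis shell (surface gaps exceed the shell radius)."""
    extent = np.asarray(spec.grid.shape) * np.asarray(spec.grid.spacing)
    placed = []  # (center, radius, effective radius)
    min_gap = spec.astro_shell_um + 2
    for _ in range(spec.n_tumors):
        for attempt in range(4000):
            r = rng.uniform(*spec.tumor_radius_range_um)
            r_eff = 1.3 * r  # lobes may extend beyond the core sphere
            if spec.vessel_cooption and len(vessel_pts):
                line = vessel_pts[int(rng.integers(len(vessel_pts)))]
                c = line[int(rng.integers(len(line)))]
            else:
                c = rng.uniform(r_eff + 1, extent - r_eff - 1)
            if np.any(c < r_eff + 1) or np.any(c > extent - r_eff - 1):
                continue
            if all(
                np.linalg.norm(c - pc) >= pr_eff + r_eff + min_gap
                for pc, _, pr_eff in placed
            ):
                placed.append((c, r, r_eff))
                break
        else:
            raise RuntimeError(
                "unplaceable scene: could not fit the requested tumors "
                "with non-intruding shells"
            )
    return placed


def _paint_tumor(spec, rng, center, radius):
    """Union-of-spheres lobular tumor; returns the digital mask and the
    analytic sphere list used for partial-volume rendering."""
    mask = np.zeros(spec.grid.shape, dtype=bool)
    spheres = [(np.asarray(center, dtype=float), float(radius))]
    for _ in range(max(spec.lobularity - 1, 0)):
        direction = rng.normal(0, 1, 3)
        direction /= np.linalg.norm(direction)
        offset = rng.uniform(0.3, 0.7) * radius
        spheres.append((np.asarray(center) + offset * direction, 0.6 * radius))
    for c, r in spheres:
        _paint_ball(mask, spec.grid, c, r)
    return mask, spheres


def _angular_cap(shell: BinaryMask, center, k: int, rng) -> np.ndarray:
    """Exactly ``k`` shell voxels forming a coherent angular cap about a
    random axis (astrocyte coverage of tumors is not spatially uniform)."""
    out = np.zeros(shell.grid.shape, dtype=bool)
    k = min(int(k), shell.count)
    if k <= 0:
        return out
    idx = np.argwhere(shell.member)
    pos = idx * np.asarray(shell.grid.spacing)
    vec = pos - np.asarray(center)
    vec /= np.maximum(np.linalg.norm(vec, axis=1, keepdims=True), 1e-12)
    axis = rng.normal(0, 1, 3)
    axis /= np.linalg.norm(axis)
    angle = np.arccos(np.clip(vec @ axis, -1, 1))
    chosen = idx[np.argsort(angle, kind="stable")[:k]]
    out[tuple(chosen.T)] = True
    return out


def _paint_edu(spec, rng, cluster: TumorCluster):
    """Place whole EdU nuclei (analytic balls) inside the tumor so each
    region's EdU fraction lands as close to its target as whole nuclei
    allow (within half a nucleus volume, well under the ±0.02 placement
    tolerance for clusters of ≥ 1000 voxels).

    With an ``edu_index_profile`` the targets are set per 10 μm inward
    zone; nuclei are kept inside their zone band where geometry permits.
    Returns the digital mask and the analytic ball list.
    """
    grid = spec.grid
    spacing = np.asarray(grid.spacing)
    r = spec.edu_spot_radius_um
    edu = np.zeros(grid.shape, dtype=bool)
    balls: list[tuple[np.ndarray, float]] = []
    depth = ndi.distance_transform_edt(cluster.mask.member, sampling=grid.spacing)

    if spec.edu_index_profile is None:
        regions = [(cluster.mask.member, spec.target_proliferative_index, (0.0, np.inf))]
    else:
        zones = concentric_zones(cluster, spec.edu_zone_um, "inward")
        regions = [
            (
                zone.member,
                float(spec.edu_index_profile((i + 0.5) / zones.n_zones)),
                ((i) * spec.edu_zone_um, (i + 1) * spec.edu_zone_um),
            )
            for i, zone in enumerate(zones.zones)
        ]

    for region, frac, (lo, hi) in regions:
        target = int(round(np.clip(frac, 0, 1) * int(region.sum())))
        # Prefer centres whose nucleus fits inside both the tumor and the
        # zone band; relax to inside-tumor, then to anywhere in the region.
        in_band = region & (depth >= r) & (depth > lo + r) & (depth <= max(hi - r, lo))
        fallbacks = [in_band, region & (depth >= r), region]
        cand = next((np.argwhere(c) for c in fallbacks if c.any()), None)
        if cand is None:
            continue
        vv = voxel_volume(grid)
        rejects = 0
        while rejects < 200:
            gap = target - int(np.count_nonzero(edu & region))
            if gap <= 0:
                break
            # Shrink the nucleus toward the remaining gap volume so the
            # final fraction converges well inside the ±0.02 band.
            r_gap = (3.0 * gap * vv / (4.0 * np.pi)) ** (1.0 / 3.0)
            r_i = float(np.clip(r_gap, 1.5, r))
            center = cand[int(rng.integers(len(cand)))] * spacing
            ball = np.zeros(grid.shape, dtype=bool)
            _paint_ball(ball, grid, center, r_i)
            ball &= cluster.mask.member
            added = int(np.count_nonzero(ball & region & ~edu))
            if added == 0 or added >= 2 * gap:
                rejects += 1  # would overshoot further than it helps
                continue
            rejects = 0
            edu |= ball
            balls.append((center, r_i))
    return edu, balls


def generate_phantom(spec: PhantomSpec) -> tuple[MultiChannelVolume, GroundTruth]:
    """Render one seeded scene: channels (DAPI, K8, GFAP, EdU, vessel) plus
    ground-truth masks and per-tumor records.

    Deterministic for a given spec (including seed). Channels are the class
    indicators scaled to the channel amplitude, blurred by a Gaussian PSF
    stand-in, then corrupted by background and noise; the truth masks are
    the pre-noise indicators.
    """
    rng = np.random.default_rng(spec.seed)
    grid = spec.grid
    extent = np.asarray(grid.shape) * np.asarray(grid.spacing)

    # Vessels first so co-opting tumors can follow a centerline.
    vessel_rng = np.random.default_rng(rng.integers(2**31))
    centerlines = [
        _walk_centerline(spec, vessel_rng) for _ in range(spec.n_vessels)
    ]
    vessel = np.zeros(grid.shape, dtype=bool)
    vessel_soft = np.zeros(grid.shape)
    for pts in centerlines:
        samples = []
        for a, b in zip(pts[:-1], pts[1:]):
            seg = np.linalg.norm(b - a)
            for t in np.arange(0.0, seg, 0.5):
                samples.append(a + t / seg * (b - a))
        if len(pts):
            samples.append(pts[-1])
        for p in samples:
            _paint_ball(vessel, grid, p, spec.vessel_radius_um)
            _paint_ball_soft(vessel_soft, grid, p, spec.vessel_radius_um)

    placements = _place_tumors(spec, rng, centerlines)
    tumor_soft = np.zeros(grid.shape)
    tumor_masks = []
    for c, r, _ in placements:
        m, spheres = _paint_tumor(spec, rng, c, r)
        tumor_masks.append(m)
        for sc, sr in spheres:
            _paint_ball_soft(tumor_soft, grid, sc, sr)
    tumor = np.zeros(grid.shape, dtype=bool)
    tumor_labels = np.zeros(grid.shape, dtype=np.int32)
    for i, m in enumerate(tumor_masks):
        tumor |= m
        tumor_labels[m] = i + 1

    vv = voxel_volume(grid)
    clusters = [
        TumorCluster(i + 1, BinaryMask(grid, m), float(m.sum()) * vv)
        for i, m in enumerate(tumor_masks)
    ]

    # Astrocyte caps: exact-coverage angular sectors of each tumor's shell.
    # A voxel may lie in two tumors' shells; painting is restricted to each
    # tumor's exclusive shell region so every stored gliosis index equals
    # the requested coverage exactly.
    shells = [surrounding_space(c, spec.astro_shell_um).member for c in clusters]
    any_shell = np.zeros(grid.shape, dtype=bool)
    for s in shells:
        any_shell |= s
    astro = np.zeros(grid.shape, dtype=bool)
    for cluster, shell_m, (center, _, _) in zip(clusters, shells, placements):
        others = np.zeros(grid.shape, dtype=bool)
        for other, s in zip(clusters, shells):
            if other.id != cluster.id:
                others |= s
        allowed = BinaryMask(grid, shell_m & ~others & ~tumor)
        k = int(round(spec.astro_shell_coverage * int(shell_m.sum())))
        cap = _angular_cap(allowed, center, k, rng)
        astro |= cap
        # Fine processes just beyond the shells: radial filaments that test
        # thin-structure preservation without touching any gliosis band.
        if spec.astro_process_length_um > 0 and cap.any():
            surf = np.argwhere(cap)
            for _ in range(6):
                p = surf[int(rng.integers(len(surf)))] * np.asarray(grid.spacing)
                direction = p - center
                direction /= max(np.linalg.norm(direction), 1e-9)
                start = np.asarray(center) + direction * (spec.astro_shell_um + 1.0)
                proc = render_tube(
                    grid, start, direction, spec.astro_process_length_um, 1.0
                )
                astro |= proc.member & ~any_shell & ~tumor

    edu = np.zeros(grid.shape, dtype=bool)
    edu_soft = np.zeros(grid.shape)
    for cluster in clusters:
        cluster_edu, balls = _paint_edu(spec, rng, cluster)
        edu |= cluster_edu
        for bc, br in balls:
            _paint_ball_soft(edu_soft, grid, bc, br)

    nuclei = tumor | edu
    nuclei_soft = np.maximum(tumor_soft, edu_soft)
    for _ in range(spec.n_nuclei):
        c = rng.uniform(0, 1, 3) * extent
        _paint_ball(nuclei, grid, c, spec.nucleus_radius_um)
        _paint_ball_soft(nuclei_soft, grid, c, spec.nucleus_radius_um)

    masks = {
        "tumor": BinaryMask(grid, tumor),
        "astrocyte": BinaryMask(grid, astro),
        "proliferating": BinaryMask(grid, edu),
        "vessel": BinaryMask(grid, vessel),
        "nuclei": BinaryMask(grid, nuclei),
    }

    records = [
        TumorTruth(
            cluster.id,
            cluster.volume_um3,
            proliferation_ratio(cluster, masks["proliferating"]),
            gliosis_index(cluster, masks["astrocyte"], spec.astro_shell_um),
        )
        for cluster in clusters
    ]

    # The astrocyte cap is a voxel-exact set (not a union of analytic
    # shapes); its partial-volume rendering ramps with the interior
    # distance so the half-intensity surface passes through the outermost
    # cap voxels instead of inflating the cap by half a voxel.
    if astro.any():
        astro_soft = np.clip(
            ndi.distance_transform_edt(astro, sampling=grid.spacing)
            / (2.0 * min(grid.spacing)),
            0.0,
            1.0,
        )
    else:
        astro_soft = np.zeros(grid.shape)
    soft = {
        "tumor": tumor_soft,
        "astrocyte": astro_soft,
        "proliferating": edu_soft,
        "vessel": vessel_soft,
        "nuclei": nuclei_soft,
    }
    sig_vox = spec.psf_sigma_um / np.asarray(grid.spacing)
    channels = []
    for class_name, channel_name in CHANNEL_FOR_CLASS.items():
        indicator = soft[class_name] * spec.channel_amplitude
        if spec.psf_sigma_um > 0:
            indicator = ndi.gaussian_filter(indicator, sig_vox, mode="nearest")
        clean = IntensityVolume(grid, indicator, channel_name)
        chan_rng = np.random.default_rng(rng.integers(2**31))
        channels.append(corrupt(clean, spec, chan_rng))

    return MultiChannelVolume(channels), GroundTruth(masks, records, tumor_labels)


def sample_training_labels(
    mask: BinaryMask,
    fraction: float,
    rng: np.random.Generator,
    boundary_um: float = 3.0,
    foreground_share: float = 1 / 3,
    boundary_share: float = 0.6,
) -> TrainingLabels:
    """Stratified sparse labels standing in for expert annotation.

    Draws ``fraction`` of all voxels without replacement: a third
    foreground (capped by the pool) and two thirds background, of which
    60% come from within ``boundary_um`` of the foreground. Experts label
    more background than foreground and concentrate background strokes
    along object outlines; without dense border examples a classifier
    absorbs the blur halo around small objects, and an even class split
    inflates the foreground prior far above its true prevalence.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    n_total = max(int(round(fraction * mask.grid.n_voxels)), 3)
    fg = np.argwhere(mask.member)
    n_fg = min(int(n_total * foreground_share), len(fg))
    n_bg = n_total - n_fg
    if n_fg == 0:
        raise ValueError("mask must contain both classes")
    if boundary_um > 0:
        halo = dilate_by_distance(mask, boundary_um).member & ~mask.member
    else:
        halo = np.zeros(mask.grid.shape, dtype=bool)
    near = np.argwhere(halo)
    far = np.argwhere(~mask.member & ~halo)
    n_near = min(int(n_bg * boundary_share), len(near))
    n_far = min(n_bg - n_near, len(far))
    if n_near + n_far == 0:
        raise ValueError("mask must contain both classes")
    picks = [fg[rng.choice(len(fg), n_fg, replace=False)]]
    if n_near:
        picks.append(near[rng.choice(len(near), n_near, replace=False)])
    if n_far:
        picks.append(far[rng.choice(len(far), n_far, replace=False)])
    coords = np.vstack(picks)
    labels = np.concatenate([np.ones(n_fg, bool), np.zeros(n_near + n_far, bool)])
    return TrainingLabels(coords, labels)
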