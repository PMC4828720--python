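"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately avoid the code paths they check: distances by
all-pairs minimisation over mask voxels, connectivity by breadth-first
flood fill, window percentiles by explicit per-voxel window extraction.
"""

from collections import deque
from itertools import product

import numpy as np
import pytest

from smart3d.core import BinaryMask, VoxelGrid


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def brute_force_distance_field(mask: BinaryMask) -> np.ndarray:
    """Minimum Euclidean distance (μm) to the mask voxels, via direct
    nearest-neighbour search (all-pairs for small masks, k-d tree above
    that) — an independent route from the distance-transform code path."""
    from scipy.spatial import cKDTree

    spacing = np.asarray(mask.grid.spacing)
    pts = np.argwhere(mask.member) * spacing
    coords = np.argwhere(np.ones(mask.grid.shape, dtype=bool)) * spacing
    if len(pts) * len(coords) <= 2e7:
        d2 = ((coords[:, None, :] - pts[None, :, :]) ** 2).sum(-1)
        out = np.sqrt(d2.min(axis=1))
    else:
        out, _ = cKDTree(pts).query(coords, k=1)
    return out.reshape(mask.grid.shape)


def flood_fill_components(member: np.ndarray, connectivity: int) -> list[set]:
    """Connected components as voxel-index sets, by BFS."""
    offsets = [
        off
        for off in product((-1, 0, 1), repeat=3)
        if off != (0, 0, 0)
        and {6: 1, 18: 2, 26: 3}[connectivity] >= sum(abs(o) for o in off)
    ]
    seen = np.zeros(member.shape, dtype=bool)
    comps = []
    for start in map(tuple, np.argwhere(member)):
        if seen[start]:
            continue
        comp = set()
        queue = deque([start])
        seen[start] = True
        while queue:
            v = queue.popleft()
            comp.add(v)
            for off in offsets:
                w = tuple(a + b for a, b in zip(v, off))
                if all(0 <= c < n for c, n in zip(w, member.shape)):
                    if member[w] and not seen[w]:
                        seen[w] = True
                        queue.append(w)
        comps.append(comp)
    return comps


def brute_force_window_percentile(
    values: np.ndarray, edge: int, percentile: float
) -> np.ndarray:
    """Per-voxel percentile of the border-clipped cubic window."""
    h = edge // 2
    out = np.empty(values.shape)
    for x, y, z in product(*(range(n) for n in values.shape)):
        w = values[
            max(x - h, 0) : x + h + 1,
            max(y - h, 0) : y + h + 1,
            max(z - h, 0) : z + h + 1,
        ]
        out[x, y, z] = np.percentile(w, percentile)
    return out


def random_mask(rng, shape, density=0.05, spacing=(1.0, 1.0, 1.0)) -> BinaryMask:
    grid = VoxelGrid(shape, spacing)
    member = rng.random(shape) < density
    if not member.any():
        member[tuple(rng.integers(0, n) for n in shape)] = True
    return BinaryMask(grid, member)
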