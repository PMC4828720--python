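"""TIFF stack I/O, MSE slice alignment, configuration and provenance.

On disk a volume is a multi-page TIFF whose pages are z-planes of (y, x)
pixels; in memory arrays are (x, y, z), so a 3-page stack of 4×5 planes
becomes a grid of shape (5, 4, 3). Voxel spacing is not stored in the TIFF;
it travels in the pipeline config / CLI flags.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import tifffile
import yaml

from .core import BinaryMask, IntensityVolume, LabelVolume, VoxelGrid

__all__ = [
    "read_stack",
    "write_stack",
    "read_mask",
    "write_mask",
    "read_labels",
    "write_labels",
    "align_slices",
    "load_config",
    "write_provenance",
]


def _to_memory(pages: np.ndarray) -> np.ndarray:
    """(z, y, x) file layout -> (x, y, z) memory layout."""
    return np.ascontiguousarray(pages.transpose(2, 1, 0))


def _to_file(values: np.ndarray) -> np.ndarray:
    return np.ascontiguousarray(values.transpose(2, 1, 0))


def _read_pages(path) -> np.ndarray:
    with tifffile.TiffFile(path) as tif:
        shapes = {p.shape for p in tif.pages}
        if len(shapes) != 1:
            raise ValueError(f"inconsistent page shapes in {path}: {sorted(shapes)}")
        data = tif.asarray()
    if data.ndim == 2:
        data = data[None]
    if data.ndim != 3:
        raise ValueError(f"unsupported TIFF layout {data.shape} in {path}")
    return data


def read_stack(
    path, spacing: tuple[float, float, float], channel_name: str = ""
) -> IntensityVolume:
    """Read a multi-page TIFF as one intensity channel."""
    data = _read_pages(path)
    if data.dtype.kind not in "uif":
        raise ValueError(f"unsupported sample format {data.dtype} in {path}")
    values = _to_memory(data)
    grid = VoxelGrid(values.shape, spacing)
    return IntensityVolume(grid, np.asarray(values, dtype=np.float64), channel_name)


def write_stack(vol: IntensityVolume, path) -> None:
    """Write an intensity volume; integer data round-trips losslessly,
    floats are stored as 32-bit."""
    values = vol.values
    if values.dtype.kind in "ui":
        out = values
    else:
        out = values.astype(np.float32)
    tifffile.imwrite(path, _to_file(out), photometric="minisblack")


def read_mask(path, spacing) -> BinaryMask:
    data = _to_memory(_read_pages(path))
    return BinaryMask(VoxelGrid(data.shape, spacing), data > 0)


def write_mask(mask: BinaryMask, path) -> None:
    tifffile.imwrite(path, _to_file(mask.member.astype(np.uint8) * 255), photometric="minisblack")


def read_labels(path, spacing) -> LabelVolume:
    data = _to_memory(_read_pages(path))
    if data.dtype.kind not in "iu":
        raise ValueError("label stacks must be integer-typed")
    return LabelVolume(VoxelGrid(data.shape, spacing), data.astype(np.int32))


def write_labels(labels: LabelVolume, path) -> None:
    dtype = np.uint16 if labels.n_labels < 2**16 else np.uint32
    tifffile.imwrite(path, _to_file(labels.label.astype(dtype)), photometric="minisblack")


def _pair_shift(a: np.ndarray, b: np.ndarray, max_shift: int) -> tuple[int, int]:
    """Integer (dx, dy) minimizing MSE between plane ``a`` and plane ``b``
    translated back by (dx, dy), over the full overlap after shifting.

    Ties break toward the smaller shift magnitude, then lexicographically.
    """
    nx, ny = a.shape
    best = None
    for dx in range(-max_shift, max_shift + 1):
        for dy in range(-max_shift, max_shift + 1):
            ax0, ax1 = max(0, -dx), min(nx, nx - dx)
            ay0, ay1 = max(0, -dy), min(ny, ny - dy)
            if ax1 <= ax0 or ay1 <= ay0:
                continue
            sub_a = a[ax0:ax1, ay0:ay1]
            sub_b = b[ax0 + dx : ax1 + dx, ay0 + dy : ay1 + dy]
            mse = float(np.mean((sub_a - sub_b) ** 2))
            key = (mse, dx * dx + dy * dy, dx, dy)
            if best is None or key < best[0]:
                best = (key, (dx, dy))
    return best[1]


def align_slices(
    stack: IntensityVolume, max_shift: int
) -> tuple[list[tuple[int, int]], IntensityVolume]:
    """Rigid per-plane alignment by exhaustive integer-shift MSE search.

    For each consecutive plane pair the integer in-plane translation
    minimizing the mean squared error on the overlap is found; cumulative
    shifts are applied (content moved back, zero-filled at the edges).
    Returns the per-plane shifts (first plane (0, 0)) and the realigned
    volume.
    """
    nx, ny, nz = stack.grid.shape
    if nz < 2:
        raise ValueError("alignment needs at least 2 planes")
    if max_shift < 0 or max_shift >= min(nx, ny):
        raise ValueError("max_shift must be >= 0 and smaller than the plane size")
    planes = [np.asarray(stack.values[:, :, k], dtype=float) for k in range(nz)]
    shifts: list[tuple[int, int]] = [(0, 0)]
    for k in range(1, nz):
        shifts.append(_pair_shift(planes[k - 1], planes[k], max_shift))
    aligned = np.zeros_like(stack.values)
    cx = cy = 0
    for k in range(nz):
        cx += shifts[k][0]
        cy += shifts[k][1]
        src = planes[k]
        # destination [x, y] <- source [x + cx, y + cy]
        dx0, dx1 = max(0, -cx), min(nx, nx - cx)
        dy0, dy1 = max(0, -cy), min(ny, ny - cy)
        if dx1 > dx0 and dy1 > dy0:
            aligned[dx0:dx1, dy0:dy1, k] = src[dx0 + cx : dx1 + cx, dy0 + cy : dy1 + cy]
    return shifts, IntensityVolume(stack.grid, aligned, stack.channel_name)


def load_config(path) -> dict:
    """Flat key-value pipeline configuration (YAML mapping)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError("config must be a flat key-value mapping")
    return cfg


def write_provenance(out_path, config: dict, seed: int | None = None) -> Path:
    """Record config hash, seed and package version beside an output file,
    sufficient to reproduce deterministic stages bit-identically."""
    from . import __version__

    payload = json.dumps(config, sort_keys=True, default=str)
    record = {
        "config_sha256": hashlib.sha256(payload.encode()).hexdigest(),
        "config": config,
        "seed": seed,
        "smart3d_version": __version__,
    }
    prov = Path(str(out_path) + ".provenance.json")
    prov.write_text(json.dumps(record, indent=2, default=str))
    return prov
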