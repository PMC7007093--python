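"""Raster grid helpers.

All grids are axis-aligned, row-major, 0-indexed numpy arrays. A fine grid
nests exactly into a coarse grid: the coarsening factor must divide both
dimensions, so every fine cell belongs to exactly one coarse cell and
area-weight interpolation is never needed. Cell areas are supplied per row
(km^2), which accommodates latitude-dependent cell sizes on a toy domain
without dragging in a map projection.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "check_nesting",
    "block_view",
    "coarsen_sum",
    "refine",
    "row_areas",
]


def check_nesting(shape: tuple[int, int], factor: int) -> tuple[int, int]:
    """Validate that ``factor`` divides both grid dimensions.

    Returns the coarse shape ``(rows // factor, cols // factor)``.
    """
    if factor < 1 or int(factor) != factor:
        raise ValueError(f"coarsening factor must be a positive integer, got {factor}")
    rows, cols = shape
    if rows % factor or cols % factor:
        raise ValueError(
            f"grid shape {shape} is not divisible by coarsening factor {factor}"
        )
    return rows // factor, cols // factor


def block_view(arr: np.ndarray, factor: int) -> np.ndarray:
    """Reshape the trailing two axes into (coarse_y, fy, coarse_x, fx) blocks."""
    *lead, rows, cols = arr.shape
    cr, cc = check_nesting((rows, cols), factor)
    return arr.reshape(*lead, cr, factor, cc, factor)


def coarsen_sum(arr: np.ndarray, factor: int) -> np.ndarray:
    """Aggregate the trailing two axes to the coarse grid by block summation."""
    if factor == 1:
        return arr.copy()
    return block_view(arr, factor).sum(axis=(-3, -1))


def refine(arr: np.ndarray, factor: int) -> np.ndarray:
    """Broadcast a coarse field onto the fine grid (each value repeated f x f)."""
    if factor == 1:
        return arr.copy()
    return np.repeat(np.repeat(arr, factor, axis=-2), factor, axis=-1)


def row_areas(cell_area_km2, shape: tuple[int, int]) -> np.ndarray:
    """Expand a scalar or per-row area spec into a full 2-D area grid (km^2)."""
    rows, cols = shape
    area = np.asarray(cell_area_km2, dtype=float)
    if area.ndim == 0:
        return np.full(shape, float(area))
    if area.ndim == 1:
        if area.size != rows:
            raise ValueError(f"per-row areas length {area.size} != {rows} rows")
        return np.broadcast_to(area[:, None], shape).copy()
    if area.shape != (rows, cols):
        raise ValueError(f"area grid shape {area.shape} != {shape}")
    return area.copy()
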