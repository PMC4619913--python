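"""Voxel-grid / world-coordinate helpers shared across the pipeline.

Points live in world millimetres; voxel indices are 0-based.  World-to-voxel
lookup rounds half-down, i.e. a coordinate exactly midway between two voxel
centres maps to the lower index.
"""

from __future__ import annotations

import numpy as np

__all__ = ["default_affine", "voxel_centers", "world_to_voxel", "voxel_to_world", "in_bounds"]


def default_affine(voxel_size=(2.0, 2.0, 2.0)) -> np.ndarray:
    """RAS+ scaling affine; voxel (i, j, k) centre at (i, j, k) * voxel_size."""
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = voxel_size
    return aff


def voxel_to_world(affine: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Map (..., 3) voxel indices to world mm coordinates."""
    idx = np.asarray(idx, dtype=float)
    return idx @ affine[:3, :3].T + affine[:3, 3]


def world_to_voxel(affine: np.ndarray, points: np.ndarray) -> np.ndarray:
    """Map (..., 3) world points to integer voxel indices (round half-down)."""
    points = np.asarray(points, dtype=float)
    inv = np.linalg.inv(affine)
    cont = points @ inv[:3, :3].T + inv[:3, 3]
    return np.ceil(cont - 0.5).astype(np.int64)


def in_bounds(idx: np.ndarray, shape: tuple[int, int, int]) -> np.ndarray:
    """Boolean mask of (..., 3) indices lying inside the grid."""
    idx = np.asarray(idx)
    ok = np.ones(idx.shape[:-1], dtype=bool)
    for axis in range(3):
        ok &= (idx[..., axis] >= 0) & (idx[..., axis] < shape[axis])
    return ok


def voxel_centers(shape: tuple[int, int, int], affine: np.ndarray) -> np.ndarray:
    """World coordinates of every voxel centre, shape (*shape, 3)."""
    grid = np.stack(
        np.meshgrid(*[np.arange(n) for n in shape], indexing="ij"), axis=-1
    ).astype(float)
    return voxel_to_world(affine, grid)
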