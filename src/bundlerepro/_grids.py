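"""Shared voxel-grid helpers.

All world coordinates are RAS mm.  A grid is a (affine, shape) pair where
``affine`` maps voxel indices to world coordinates of voxel centers.
Voxel ownership is half-open: a world point belongs to the voxel whose
index is round(inv(affine) @ x), with exact .5 ties broken toward the
lower index.
"""
from __future__ import annotations

from typing import NamedTuple, Sequence

import numpy as np


class GridSpec(NamedTuple):
    """A voxel grid: 4x4 voxel-to-world affine plus integer shape."""

    affine: np.ndarray
    shape: tuple[int, int, int]

    @property
    def voxel_sizes(self) -> np.ndarray:
        return voxel_sizes(self.affine)


def voxel_sizes(affine: np.ndarray) -> np.ndarray:
    """Physical voxel edge lengths (mm) from the affine columns."""
    return np.linalg.norm(np.asarray(affine)[:3, :3], axis=0)


def world_to_voxel(affine: np.ndarray, points: np.ndarray) -> np.ndarray:
    """Map world-mm points (N,3) to continuous voxel coordinates."""
    inv = np.linalg.inv(affine)
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    return pts @ inv[:3, :3].T + inv[:3, 3]

def voxel_to_world(affine: np.ndarray, indices: np.ndarray) -> np.ndarray:
    idx = np.atleast_2d(np.asarray(indices, dtype=float))
    aff = np.asarray(affine)
    return idx @ aff[:3, :3].T + aff[:3, 3]


def points_to_indices(affine: np.ndarray, points: np.ndarray) -> np.ndarray:
    """Nearest-voxel indices with .5 ties broken toward the lower index."""
    v = world_to_voxel(affine, points)
    return np.ceil(v - 0.5).astype(np.int64)


def in_bounds(indices: np.ndarray, shape: Sequence[int]) -> np.ndarray:
    idx = np.atleast_2d(indices)
    ok = np.ones(len(idx), dtype=bool)
    for ax, n in enumerate(shape):
        ok &= (idx[:, ax] >= 0) & (idx[:, ax] < n)
    return ok


def isotropic_grid_like(
    affine: np.ndarray, shape: Sequence[int], spacing: float = 1.0
) -> GridSpec:
    """A grid with the same orientation and field of view, at ``spacing`` mm.

    The new grid shares the source grid's direction cosines and outer
    corner; its shape is the smallest that covers the source field of view.
    """
    aff = np.asarray(affine, dtype=float)
    vs = voxel_sizes(aff)
    dirs = aff[:3, :3] / vs  # unit direction vectors, one per column
    extent = vs * np.asarray(shape)
    new_shape = tuple(int(np.ceil(e / spacing - 1e-9)) for e in extent)
    # world position of the [-0.5,-0.5,-0.5] grid corner is preserved
    corner = aff[:3, 3] - aff[:3, :3] @ np.array([0.5, 0.5, 0.5])
    new_aff = np.eye(4)
    new_aff[:3, :3] = dirs * spacing
    new_aff[:3, 3] = corner + new_aff[:3, :3] @ np.array([0.5, 0.5, 0.5])
    return GridSpec(new_aff, new_shape)


def grids_close(a_aff, a_shape, b_aff, b_shape, tol: float = 1e-4) -> bool:
    return tuple(a_shape) == tuple(b_shape) and bool(
        np.allclose(a_aff, b_aff, atol=tol)
    )
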