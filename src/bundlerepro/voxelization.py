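"""Streamline and probability-map voxelization to binary bundle masks.

The common currency of all bundle comparisons is a binary mask resampled
at 1 mm isotropic resolution.  Streamline bundles are binarized at a
streamline density of 1; probability maps at an inclusive threshold
(default 2.5e-4).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np

from ._grids import (
    GridSpec,
    grids_close,
    in_bounds,
    isotropic_grid_like,
    points_to_indices,
    voxel_sizes,
    voxel_to_world,
)
from .io_bundles import Tractogram, Volume

DEFAULT_PROBABILITY_THRESHOLD = 2.5e-4
#: sub-voxel sampling step (mm) when walking streamline segments
SEGMENT_STEP_MM = 0.1


@dataclass
class DensityMap:
    """Per-voxel count of distinct streamlines visiting each voxel."""

    counts: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.affine = np.asarray(self.affine, dtype=float)
        if np.any(self.counts < 0):
            raise ValueError("density counts must be nonnegative")

    @property
    def voxel_sizes(self) -> np.ndarray:
        return voxel_sizes(self.affine)

    @property
    def grid(self) -> GridSpec:
        return GridSpec(self.affine, tuple(self.counts.shape))


@dataclass
class BundleMask:
    """A binary bundle mask; ``empty`` flags an all-zero mask."""

    mask: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask).astype(bool)
        self.affine = np.asarray(self.affine, dtype=float)

    @property
    def empty(self) -> bool:
        return not bool(self.mask.any())

    @property
    def voxel_sizes(self) -> np.ndarray:
        return voxel_sizes(self.affine)

    @property
    def grid(self) -> GridSpec:
        return GridSpec(self.affine, tuple(self.mask.shape))

    @property
    def volume_mm3(self) -> float:
        return float(self.mask.sum() * np.prod(self.voxel_sizes))


def _sample_segments(points: np.ndarray, step: float) -> np.ndarray:
    """Points along a polyline at <= ``step`` mm spacing, vertices included."""
    out = [points[:1]]
    deltas = np.diff(points, axis=0)
    seg_len = np.linalg.norm(deltas, axis=1)
    for p, d, L in zip(points[:-1], deltas, seg_len):
        n = max(int(np.ceil(L / step)), 1)
        t = np.arange(1, n + 1)[:, None] / n
        out.append(p + t * d)
    return np.vstack(out)


def streamlines_to_density(
    t: Tractogram,
    grid_affine: np.ndarray,
    grid_shape: tuple[int, int, int],
    step: float = SEGMENT_STEP_MM,
) -> DensityMap:
    """Count distinct streamlines visiting each voxel of the given grid.

    Each segment is walked at ``step`` mm and voxel visits are
    de-duplicated per streamline, so a streamline increments a voxel at
    most once.  Streamlines entirely outside the grid contribute nothing
    (a warning reports how many).
    """
    grid_affine = np.asarray(grid_affine, dtype=float)
    counts = np.zeros(tuple(grid_shape), dtype=np.int32)
    n_outside = 0
    for s in t.streamlines:
        pts = _sample_segments(s, step)
        idx = points_to_indices(grid_affine, pts)
        idx = idx[in_bounds(idx, grid_shape)]
        if len(idx) == 0:
            n_outside += 1
            continue
        uniq = np.unique(idx, axis=0)
        counts[uniq[:, 0], uniq[:, 1], uniq[:, 2]] += 1
    if n_outside:
        warnings.warn(
            f"{n_outside} streamline(s) entirely outside the target grid",
            stacklevel=2,
        )
    return DensityMap(counts, grid_affine)


def density_to_mask(
    d: DensityMap,
    threshold: int = 1,
    target: Optional[GridSpec] = None,
    standardize: bool = True,
) -> BundleMask:
    """Binarize a density map at ``counts >= threshold`` and standardize.

    With ``standardize`` the result is resampled to a 1 mm isotropic grid
    (``target`` if given, else one covering the source field of view).
    """
    if threshold < 1:
        raise ValueError("density threshold must be >= 1")
    mask = BundleMask(d.counts >= threshold, d.affine)
    if not standardize:
        return mask
    return standardize_mask(mask, target)


def probability_to_mask(
    p: Volume,
    threshold: float = DEFAULT_PROBABILITY_THRESHOLD,
    target: Optional[GridSpec] = None,
    standardize: bool = True,
) -> BundleMask:
    """Binarize a probability / visitation map at an inclusive threshold."""
    if np.any(p.data < 0):
        raise ValueError("probability map contains negative values")
    mask = BundleMask(p.data >= threshold, p.affine)
    if not standardize:
        return mask
    return standardize_mask(mask, target)


def standardize_mask(m: BundleMask, target: Optional[GridSpec] = None) -> BundleMask:
    """Nearest-neighbor resample a binary mask onto a 1 mm isotropic grid.

    If the source already sits on the target grid it is returned as-is.
    A warning is raised when nonzero source voxels fall outside the
    target field of view.
    """
    if target is None:
        if np.allclose(m.voxel_sizes, 1.0, atol=1e-6):
            return m
        target = isotropic_grid_like(m.affine, m.mask.shape, spacing=1.0)
    if grids_close(m.affine, m.mask.shape, target.affine, target.shape):
        return m
    # map every target voxel center into the source grid
    tgt_idx = np.indices(target.shape).reshape(3, -1).T
    world = voxel_to_world(target.affine, tgt_idx)
    src_idx = points_to_indices(m.affine, world)
    ok = in_bounds(src_idx, m.mask.shape)
    out = np.zeros(target.shape, dtype=bool)
    vals = np.zeros(len(src_idx), dtype=bool)
    vals[ok] = m.mask[src_idx[ok, 0], src_idx[ok, 1], src_idx[ok, 2]]
    out[tgt_idx[:, 0], tgt_idx[:, 1], tgt_idx[:, 2]] = vals
    # clipping check: nonzero source voxel centers that leave the target FOV
    src_nz = np.argwhere(m.mask)
    if len(src_nz):
        nz_world = voxel_to_world(m.affine, src_nz)
        nz_tgt = points_to_indices(target.affine, nz_world)
        clipped = int((~in_bounds(nz_tgt, target.shape)).sum())
        if clipped:
            warnings.warn(
                f"target grid truncates {clipped} nonzero source voxel(s)",
                stacklevel=2,
            )
    return BundleMask(out, np.asarray(target.affine, dtype=float))
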