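"""The 12 bundle geometry descriptors.

Length features: mean streamline length, span (distance between the two
end-region centroids), equivalent-cylinder diameter, and the average
disc-equivalent radius of the two end regions.  Area features: total
exposed voxel surface area and total end-region area.  Volume features:
total, trunk and branch volume.  Dimensionless shape features: curl
(length/span), elongation (length/diameter) and irregularity (surface
area relative to the equivalent cylinder's lateral surface).

The normative definitions used here treat the bundle as an equivalent
cylinder of the bundle's volume and mean length:

    diameter     = 2 * sqrt(volume / (pi * mean_length))
    elongation   = mean_length / diameter
    irregularity = surface_area / (pi * diameter * mean_length)

so a perfect digital cylinder has irregularity close to 1.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, fields
from typing import Optional

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

from ._grids import in_bounds, points_to_indices
from .io_bundles import Tractogram
from .voxelization import BundleMask, density_to_mask, streamlines_to_density

#: single-linkage cutoff (mm) for the main endpoint cluster per side,
#: used to separate trunk from branch streamlines
TRUNK_LINKAGE_MM = 10.0

FEATURE_NAMES = (
    "mean_length",
    "span",
    "diameter",
    "end_radius",
    "surface_area",
    "end_area",
    "volume",
    "trunk_volume",
    "branch_volume",
    "curl",
    "elongation",
    "irregularity",
)


class DegenerateBundleError(ValueError):
    """Geometry that admits no well-defined features (e.g. zero span)."""


@dataclass
class ShapeFeatureSet:
    """The 12 scalar geometry descriptors of one bundle.

    Lengths in mm, areas in mm², volumes in mm³; curl, elongation and
    irregularity are dimensionless.
    """

    mean_length: float
    span: float
    diameter: float
    end_radius: float
    surface_area: float
    end_area: float
    volume: float
    trunk_volume: float
    branch_volume: float
    curl: float
    elongation: float
    irregularity: float

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


# ---------------------------------------------------------------------------
# orientation

def _endpoints(t: Tractogram) -> tuple[np.ndarray, np.ndarray]:
    starts = np.array([s[0] for s in t.streamlines])
    ends = np.array([s[-1] for s in t.streamlines])
    return starts, ends


def orient_streamlines(t: Tractogram) -> Tractogram:
    """Flip streamlines so they all run the same nominal direction.

    The two endpoint sides are found by splitting all endpoints on the
    sign of their projection onto the first principal axis (relative to
    the overall endpoint centroid); side A is the one with the smaller
    mean projection.  Each streamline is flipped so its start is the
    endpoint closer to side A's centroid.
    """
    starts, ends = _endpoints(t)
    pts = np.vstack([starts, ends])
    centered = pts - pts.mean(axis=0)
    if np.allclose(centered, 0.0, atol=1e-9):
        raise DegenerateBundleError("all endpoints coincide")
    # principal axis of the endpoint cloud
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    proj = centered @ vt[0]
    side_a = proj < np.median(proj) if np.ptp(proj) < 1e-12 else proj <= 0
    if side_a.all() or not side_a.any():
        # all on one side of zero: split at the median instead
        side_a = proj <= np.median(proj)
    c_a = pts[side_a].mean(axis=0)
    flipped = []
    for s in t.streamlines:
        d_start = np.linalg.norm(s[0] - c_a)
        d_end = np.linalg.norm(s[-1] - c_a)
        flipped.append(s[::-1].copy() if d_end < d_start else s)
    return Tractogram(
        flipped,
        reference_affine=t.reference_affine,
        reference_shape=t.reference_shape,
    )


# ---------------------------------------------------------------------------
# feature groups

def length_features(t: Tractogram) -> tuple[float, float, float]:
    """(mean_length, span, curl) of an oriented tractogram.

    Span is the distance between the centroid of start points and the
    centroid of end points; curl = mean_length / span.
    """
    starts, ends = _endpoints(t)
    mean_length = float(t.lengths().mean())
    span = float(np.linalg.norm(starts.mean(axis=0) - ends.mean(axis=0)))
    if span <= 0:
        raise DegenerateBundleError("zero span: curl is undefined")
    return mean_length, span, mean_length / span


def _exposed_faces(mask: np.ndarray) -> int:
    """Count exposed voxel faces under 6-connectivity."""
    m = np.asarray(mask, dtype=bool)
    total = 0
    for ax in range(3):
        padded = np.pad(m, [(1, 1) if i == ax else (0, 0) for i in range(3)])
        diff = padded.astype(np.int8)
        total += int(np.abs(np.diff(diff, axis=ax)).sum())
    return total


def volume_area_features(
    m: BundleMask, mean_length: float
) -> tuple[float, float, float, float, float]:
    """(volume, surface_area, diameter, elongation, irregularity).

    Requires a standardized 1 mm mask; the diameter is that of the
    cylinder with the bundle's volume and mean length.
    """
    if m.empty:
        raise DegenerateBundleError("empty mask: volume features undefined")
    vox = float(np.prod(m.voxel_sizes))
    face = float(m.voxel_sizes[0] * m.voxel_sizes[1])  # isotropic after standardization
    volume = float(m.mask.sum()) * vox
    surface_area = _exposed_faces(m.mask) * face
    diameter = 2.0 * np.sqrt(volume / (np.pi * mean_length))
    elongation = mean_length / diameter
    irregularity = surface_area / (np.pi * diameter * mean_length)
    return volume, surface_area, diameter, elongation, irregularity


def end_region_features(t: Tractogram, m: BundleMask) -> tuple[float, float]:
    """(end_area, end_radius) from endpoint-occupied voxels.

    End region k is the set of mask-grid voxels containing at least one
    side-k endpoint; end_area sums both regions, end_radius averages the
    two disc-equivalent radii sqrt(area_k / pi).
    """
    starts, ends = _endpoints(t)
    face = float(m.voxel_sizes[0] * m.voxel_sizes[1])
    areas = []
    for side_pts in (starts, ends):
        idx = points_to_indices(m.affine, side_pts)
        ok = in_bounds(idx, m.mask.shape)
        if not ok.any():
            warnings.warn("an end region has no endpoints inside the grid", stacklevel=2)
            areas.append(0.0)
            continue
        areas.append(len(np.unique(idx[ok], axis=0)) * face)
    end_area = float(sum(areas))
    end_radius = float(np.mean([np.sqrt(a / np.pi) for a in areas]))
    return end_area, end_radius


def _main_cluster(points: np.ndarray, cutoff: float) -> np.ndarray:
    """Boolean membership of the largest single-linkage cluster."""
    if len(points) == 1:
        return np.array([True])
    d = pdist(points)
    if len(d) == 0 or d.max() <= cutoff:
        return np.ones(len(points), dtype=bool)
    labels = fcluster(linkage(d, method="single"), t=cutoff, criterion="distance")
    counts = np.bincount(labels)
    # deterministic tie-break: lowest label among the largest clusters
    main = int(np.argmax(counts))
    return labels == main


def trunk_branch(
    t: Tractogram, m: BundleMask, linkage_mm: float = TRUNK_LINKAGE_MM
) -> tuple[float, float]:
    """(trunk_volume, branch_volume) of an oriented bundle.

    Core streamlines are those whose both endpoints fall in the main
    endpoint cluster of their side (single linkage at ``linkage_mm``);
    the trunk is the density-1 mask of the core streamlines on the same
    grid, and branch volume is the remainder of the total volume.
    """
    starts, ends = _endpoints(t)
    core = _main_cluster(starts, linkage_mm) & _main_cluster(ends, linkage_mm)
    vox = float(np.prod(m.voxel_sizes))
    volume = float(m.mask.sum()) * vox
    if not core.any():
        warnings.warn("no core streamlines found; trunk volume set to 0", stacklevel=2)
        return 0.0, volume
    core_t = Tractogram(
        [s for s, c in zip(t.streamlines, core) if c],
        reference_affine=t.reference_affine,
        reference_shape=t.reference_shape,
    )
    core_density = streamlines_to_density(core_t, m.affine, m.mask.shape)
    core_mask = density_to_mask(core_density, threshold=1, standardize=False)
    # the trunk lives inside the bundle mask by construction
    trunk_volume = float((core_mask.mask & m.mask).sum()) * vox
    return trunk_volume, volume - trunk_volume


def compute_shape_features(
    t: Tractogram, m: BundleMask, linkage_mm: float = TRUNK_LINKAGE_MM
) -> ShapeFeatureSet:
    """All 12 descriptors for one (tractogram, standardized mask) pair."""
    oriented = orient_streamlines(t)
    mean_length, span, curl = length_features(oriented)
    volume, surface_area, diameter, elongation, irregularity = volume_area_features(
        m, mean_length
    )
    end_area, end_radius = end_region_features(oriented, m)
    trunk_volume, branch_volume = trunk_branch(oriented, m, linkage_mm)
    return ShapeFeatureSet(
        mean_length=mean_length,
        span=span,
        diameter=diameter,
        end_radius=end_radius,
        surface_area=surface_area,
        end_area=end_area,
        volume=volume,
        trunk_volume=trunk_volume,
        branch_volume=branch_volume,
        curl=curl,
        elongation=elongation,
        irregularity=irregularity,
    )
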