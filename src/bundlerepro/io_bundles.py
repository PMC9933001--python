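"""Streamline, volume and study-manifest I/O.

Every tractogram is converted on read to a single internal convention:
streamline points in world RAS mm, together with the reference voxel grid
(affine + shape) the bundle was produced on.  TRK files store their own
voxel-space dialect; nibabel undoes it on load.  TCK headers carry no
reference grid, so an identity affine is used unless the caller supplies
a reference image.
"""
from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import nibabel as nib
import numpy as np
import yaml

from ._grids import GridSpec, voxel_sizes

#: Confound identifiers used in the source study design.  User-defined
#: ids are allowed in addition to these.
KNOWN_CONFOUNDS = (
    "RESCAN",
    "SCAN1",
    "SCAN2",
    "VEN1",
    "VEN2",
    "RES1",
    "RES2",
    "DIR1",
    "DIR2",
    "BVAL",
    # generic aliases used by the synthetic study
    "SCAN",
    "RES",
    "DIR",
)


class TractogramFormatError(ValueError):
    """Unreadable or unsupported streamline file."""


class EmptyTractogramError(ValueError):
    """A streamline file that contains zero streamlines."""


class VolumeShapeError(ValueError):
    """A volume whose payload is not 3-D (modulo singleton trailing dims)."""


class ManifestError(ValueError):
    """An invalid study manifest."""


@dataclass
class Tractogram:
    """A bundle of streamlines in world RAS mm.

    Parameters
    ----------
    streamlines
        List of (N_i, 3) float arrays, each with >= 2 points.
    reference_affine
        4x4 voxel-to-world map of the grid the bundle belongs to.
    reference_shape
        Shape of that grid, or ``None`` when unknown (TCK input).
    """

    streamlines: list[np.ndarray]
    reference_affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    reference_shape: Optional[tuple[int, int, int]] = None

    def __post_init__(self) -> None:
        self.streamlines = [np.asarray(s, dtype=np.float64) for s in self.streamlines]
        for s in self.streamlines:
            if s.ndim != 2 or s.shape[1] != 3:
                raise ValueError("each streamline must be an (N, 3) array")
            if len(s) < 2:
                raise ValueError("each streamline must have >= 2 points")
            if not np.all(np.isfinite(s)):
                raise ValueError("streamline coordinates must be finite")
        self.reference_affine = np.asarray(self.reference_affine, dtype=float)
        if self.reference_affine.shape != (4, 4):
            raise ValueError("reference_affine must be 4x4")
        if abs(np.linalg.det(self.reference_affine)) < 1e-12:
            raise ValueError("reference_affine must be invertible")

    @property
    def n_streamlines(self) -> int:
        return len(self.streamlines)

    def lengths(self) -> np.ndarray:
        """Polyline arc length (mm) of every streamline."""
        return np.array(
            [np.linalg.norm(np.diff(s, axis=0), axis=1).sum() for s in self.streamlines]
        )


@dataclass
class Volume:
    """A 3-D scalar volume with its voxel-to-world affine."""

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 3:
            raise VolumeShapeError(f"expected 3-D data, got shape {self.data.shape}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume data must be finite")
        if np.any(voxel_sizes(self.affine) <= 0):
            raise ValueError("voxel sizes must be strictly positive")

    @property
    def voxel_sizes(self) -> np.ndarray:
        return voxel_sizes(self.affine)

    @property
    def grid(self) -> GridSpec:
        return GridSpec(self.affine, tuple(self.data.shape))


@dataclass
class StudyManifest:
    """Declarative description of a bundle-reproducibility study.

    ``datasets`` maps a dataset id to a dict with at least a ``bundles``
    path template containing ``{subject}`` / ``{pathway}`` / ``{dataset}``
    placeholders, and optionally ``dwi`` / ``bval`` / ``bvec`` templates
    and a native ``voxel_size`` in mm.
    """

    subjects: list[str]
    pathways: list[str]
    datasets: dict[str, dict]
    contrasts: list[tuple[str, str, str]]
    reference_dataset: str
    grid: Optional[str] = None  # path to the study-common reference image
    root: str = "."

    def __post_init__(self) -> None:
        declared = set(self.datasets)
        if self.reference_dataset not in declared:
            raise ManifestError(
                f"reference_dataset {self.reference_dataset!r} is not declared"
            )
        for confound, a, b in self.contrasts:
            for d in (a, b):
                if d not in declared:
                    raise ManifestError(
                        f"contrast {confound!r} references undeclared dataset {d!r}"
                    )

    def bundle_path(self, dataset: str, subject: str, pathway: str) -> str:
        tpl = self.datasets[dataset]["bundles"]
        return os.path.join(
            self.root, tpl.format(subject=subject, dataset=dataset, pathway=pathway)
        )

    def dwi_paths(self, dataset: str, subject: str) -> Optional[dict[str, str]]:
        entry = self.datasets[dataset]
        if "dwi" not in entry:
            return None
        fmt = lambda k: os.path.join(
            self.root, entry[k].format(subject=subject, dataset=dataset)
        )
        return {"dwi": fmt("dwi"), "bval": fmt("bval"), "bvec": fmt("bvec")}


# ---------------------------------------------------------------------------
# streamlines

def read_tractogram(path: str, reference: Optional[Volume] = None) -> Tractogram:
    """Load a TRK/TCK file into world RAS mm.

    Raises :class:`TractogramFormatError` on an unreadable header and
    :class:`EmptyTractogramError` when the file holds no streamlines.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    try:
        tf = nib.streamlines.load(path)
    except Exception as exc:  # nibabel raises assorted header errors
        raise TractogramFormatError(f"cannot read streamline file {path}: {exc}")
    sl = [np.asarray(s, dtype=np.float64) for s in tf.streamlines]
    if len(sl) == 0:
        raise EmptyTractogramError(f"{path} contains zero streamlines")
    header = tf.header
    if reference is not None:
        affine, shape = reference.affine, tuple(reference.data.shape)
    elif isinstance(tf, nib.streamlines.TrkFile):
        affine = np.asarray(header["voxel_to_rasmm"], dtype=float)
        shape = tuple(int(v) for v in header["dimensions"])
    else:  # TCK: header has no grid
        affine, shape = np.eye(4), None
    return Tractogram(sl, reference_affine=affine, reference_shape=shape)


def write_tractogram(t: Tractogram, path: str) -> None:
    """Write a tractogram as TRK or TCK depending on the file suffix."""
    sl = nib.streamlines.Tractogram(t.streamlines, affine_to_rasmm=np.eye(4))
    if path.endswith(".trk"):
        header = {}
        if t.reference_shape is not None:
            header["voxel_to_rasmm"] = t.reference_affine.astype(np.float32)
            header["dimensions"] = np.asarray(t.reference_shape, dtype=np.int16)
            header["voxel_sizes"] = voxel_sizes(t.reference_affine).astype(np.float32)
        nib.streamlines.save(sl, path, header=header)
    elif path.endswith(".tck"):
        nib.streamlines.save(sl, path)
    else:
        raise TractogramFormatError(f"unsupported streamline format: {path}")


# ---------------------------------------------------------------------------
# volumes

def read_volume(path: str) -> Volume:
    """Load a 3-D NIfTI volume (singleton trailing dimensions squeezed)."""
    img = nib.load(path)
    data = np.asanyarray(img.dataobj)
    while data.ndim > 3 and data.shape[-1] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise VolumeShapeError(
            f"{path}: expected a 3-D volume, got shape {data.shape}"
        )
    return Volume(np.asarray(data, dtype=np.float64), np.asarray(img.affine))


def write_volume(v: Volume, path: str, dtype=np.float32) -> None:
    nib.save(nib.Nifti1Image(v.data.astype(dtype), v.affine), path)


def read_dwi(path: str) -> tuple[np.ndarray, np.ndarray]:
    """Load a 4-D DWI NIfTI; returns (data, affine)."""
    img = nib.load(path)
    data = np.asanyarray(img.dataobj)
    if data.ndim != 4:
        raise VolumeShapeError(f"{path}: expected 4-D DWI, got shape {data.shape}")
    return np.asarray(data, dtype=np.float64), np.asarray(img.affine)


def write_dwi(data: np.ndarray, affine: np.ndarray, path: str) -> None:
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float32), affine), path)


# ---------------------------------------------------------------------------
# manifest

def read_manifest(path: str) -> StudyManifest:
    """Parse and validate a YAML study manifest.

    Relative paths inside the manifest are resolved against its directory.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, Mapping):
        raise ManifestError(f"{path}: manifest must be a mapping")
    missing = {"subjects", "pathways", "datasets", "reference_dataset"} - set(raw)
    if missing:
        raise ManifestError(f"{path}: missing manifest keys {sorted(missing)}")
    contrasts = [tuple(c) for c in raw.get("contrasts", [])]
    for c in contrasts:
        if len(c) != 3:
            raise ManifestError(f"contrast {c!r} must be (confound, dataset_a, dataset_b)")
    return StudyManifest(
        subjects=[str(s) for s in raw["subjects"]],
        pathways=[str(p) for p in raw["pathways"]],
        datasets={str(k): dict(v) for k, v in raw["datasets"].items()},
        contrasts=contrasts,
        reference_dataset=str(raw["reference_dataset"]),
        grid=raw.get("grid"),
        root=os.path.dirname(os.path.abspath(path)),
    )


def write_manifest(m: StudyManifest, path: str) -> None:
    doc = {
        "subjects": list(m.subjects),
        "pathways": list(m.pathways),
        "datasets": m.datasets,
        "contrasts": [list(c) for c in m.contrasts],
        "reference_dataset": m.reference_dataset,
    }
    if m.grid is not None:
        doc["grid"] = m.grid
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=True)


def read_bvals_bvecs(bval_path: str, bvec_path: str) -> tuple[np.ndarray, np.ndarray]:
    """FSL-style whitespace-separated b-values and gradient directions."""
    bvals = np.loadtxt(bval_path).ravel()
    bvecs = np.loadtxt(bvec_path)
    if bvecs.shape[0] == 3 and bvecs.shape != (3, 3):
        bvecs = bvecs.T
    if bvecs.ndim != 2 or bvecs.shape[1] != 3:
        raise ValueError(f"bvec file {bvec_path} is not 3xN or Nx3")
    if len(bvals) != len(bvecs):
        raise ValueError("bval/bvec length mismatch")
    return bvals, bvecs


def write_bvals_bvecs(bvals: np.ndarray, bvecs: np.ndarray, bval_path: str, bvec_path: str) -> None:
    np.savetxt(bval_path, np.asarray(bvals)[None, :], fmt="%.1f")
    np.savetxt(bvec_path, np.asarray(bvecs).T, fmt="%.8f")
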