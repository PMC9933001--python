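"""Synthetic bundle studies and DWI signals with known ground truth.

The generator emulates the structure of a multi-scanner bundle
reproducibility study: per subject, one reference "dataset" and one
perturbed dataset per confound, where each confound maps to a geometric
perturbation model —

* ``jitter``       rigid per-streamline Gaussian shifts (scan/rescan and
                   scanner noise),
* ``dropout``      random removal of a streamline fraction (direction-count
                   effects),
* ``affine``       a global affine applied to all points,
* ``radius_scale`` dilation/erosion of the tube about its centerline
                   (systematic vendor-style bias),
* ``resample``     voxelization on a coarser native grid (resolution
                   effects; applied at the grid level, not to streamlines).

Confound severities default to the ordering observed in multi-scanner
studies of bundle reconstruction: rescan mildest, cross-scanner larger,
resolution change most disruptive.

All randomness flows from explicit integer seeds, so a study is
bit-reproducible.
"""
from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from ._grids import GridSpec
from .io_bundles import (
    StudyManifest,
    Tractogram,
    Volume,
    write_bvals_bvecs,
    write_dwi,
    write_manifest,
    write_tractogram,
    write_volume,
)
from .microstructure import DWIScheme


@dataclass
class BundleSpec:
    """Parametric description of one synthetic bundle.

    ``kind`` selects the centerline: a straight segment of ``length``
    along +x, a circular arc of ``radius``/``angle_deg`` in the x-y
    plane, or a helix of ``radius``, ``pitch`` (mm rise per turn) and
    ``turns`` about +z.  Streamlines are the centerline plus a smooth
    random radial offset (SD ``tube_sd``) that is constant along the
    streamline with a low-frequency cosine wobble on top.
    """

    kind: str = "arc"
    length: float = 60.0
    radius: float = 30.0
    angle_deg: float = 180.0
    pitch: float = 15.0
    turns: float = 1.5
    n_streamlines: int = 300
    tube_sd: float = 1.0
    step: float = 1.0
    seed: int = 0
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if self.tube_sd < 0 or self.step <= 0 or self.n_streamlines < 1:
            raise ValueError("invalid bundle spec")
        if self.kind not in ("straight", "arc", "helix"):
            raise ValueError(f"unknown centerline kind {self.kind!r}")


@dataclass
class PerturbationSpec:
    """One confound-emulating perturbation of a bundle."""

    model: str  # jitter | dropout | affine | radius_scale | resample
    magnitude: float | np.ndarray = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model not in ("jitter", "dropout", "affine", "radius_scale", "resample"):
            raise ValueError(f"unknown perturbation model {self.model!r}")
        if self.model == "dropout" and not (0.0 <= float(self.magnitude) < 1.0):
            raise ValueError("dropout fraction must be in [0, 1)")
        if self.model == "radius_scale" and float(self.magnitude) <= 0:
            raise ValueError("radius scale must be positive")


@dataclass
class StudyCondition:
    """Perturbations plus optional native voxel size for one confound."""

    perturbations: list[PerturbationSpec] = field(default_factory=list)
    voxel_size: Optional[float] = None  # native grid spacing (mm); None = reference


#: Default confound plan: ten contrasts mirroring a scan-rescan /
#: cross-scanner / cross-vendor / resolution / directions / b-value design.
def default_confound_plan() -> dict[str, StudyCondition]:
    return {
        "RESCAN": StudyCondition([PerturbationSpec("jitter", 0.5)]),
        "SCAN1": StudyCondition([PerturbationSpec("jitter", 1.0)]),
        "SCAN2": StudyCondition(
            [PerturbationSpec("jitter", 1.25), PerturbationSpec("radius_scale", 1.05)]
        ),
        "VEN1": StudyCondition(
            [PerturbationSpec("jitter", 1.0), PerturbationSpec("radius_scale", 1.10)]
        ),
        "VEN2": StudyCondition(
            [PerturbationSpec("jitter", 1.0), PerturbationSpec("radius_scale", 0.90)]
        ),
        "RES1": StudyCondition([PerturbationSpec("jitter", 1.5)], voxel_size=1.5),
        "RES2": StudyCondition([PerturbationSpec("jitter", 2.0)], voxel_size=2.4),
        "DIR1": StudyCondition(
            [PerturbationSpec("jitter", 0.5), PerturbationSpec("dropout", 0.30)]
        ),
        "DIR2": StudyCondition(
            [PerturbationSpec("jitter", 0.5), PerturbationSpec("dropout", 0.15)]
        ),
        "BVAL": StudyCondition([PerturbationSpec("jitter", 0.3)]),
    }


#: Reduced three-confound plan for compact studies: rescan mildest,
#: cross-scanner intermediate, resolution most disruptive.
def small_confound_plan() -> dict[str, StudyCondition]:
    return {
        "RESCAN": StudyCondition([PerturbationSpec("jitter", 0.5)]),
        "SCAN": StudyCondition(
            [PerturbationSpec("jitter", 1.25), PerturbationSpec("radius_scale", 1.05)]
        ),
        "RES": StudyCondition([PerturbationSpec("jitter", 2.0)], voxel_size=2.4),
    }


# ---------------------------------------------------------------------------
# centerlines and bundles

def centerline_points(spec: BundleSpec) -> np.ndarray:
    """Centerline polyline at ``spec.step`` mm spacing."""
    if spec.kind == "straight":
        n = max(int(np.ceil(spec.length / spec.step)), 1)
        s = np.linspace(0.0, spec.length, n + 1)
        pts = np.column_stack([s, np.zeros_like(s), np.zeros_like(s)])
    elif spec.kind == "arc":
        theta = np.deg2rad(spec.angle_deg)
        arc_len = spec.radius * theta
        n = max(int(np.ceil(arc_len / spec.step)), 2)
        a = np.linspace(0.0, theta, n + 1)
        pts = np.column_stack(
            [spec.radius * np.sin(a), spec.radius * (1.0 - np.cos(a)), np.zeros_like(a)]
        )
    else:  # helix
        theta = 2.0 * np.pi * spec.turns
        arc_len = theta * np.sqrt(spec.radius**2 + (spec.pitch / (2 * np.pi)) ** 2)
        n = max(int(np.ceil(arc_len / spec.step)), 2)
        a = np.linspace(0.0, theta, n + 1)
        pts = np.column_stack(
            [
                spec.radius * np.cos(a) - spec.radius,
                spec.radius * np.sin(a),
                spec.pitch * a / (2 * np.pi),
            ]
        )
    return pts + np.asarray(spec.origin, dtype=float)


def _frames(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two unit normals per centerline point, orthogonal to the tangent."""
    tang = np.gradient(points, axis=0)
    tang /= np.linalg.norm(tang, axis=1, keepdims=True)
    ref = np.array([0.0, 0.0, 1.0])
    n1 = np.cross(tang, ref)
    bad = np.linalg.norm(n1, axis=1) < 1e-8
    if bad.any():
        n1[bad] = np.cross(tang[bad], np.array([1.0, 0.0, 0.0]))
    n1 /= np.linalg.norm(n1, axis=1, keepdims=True)
    n2 = np.cross(tang, n1)
    n2 /= np.linalg.norm(n2, axis=1, keepdims=True)
    return n1, n2


def generate_bundle(spec: BundleSpec) -> Tractogram:
    """Sample a coherent tube of streamlines around the centerline.

    Each streamline's radial offset is a constant draw (SD ``tube_sd``)
    plus a cosine wobble of ~30% amplitude and random phase, giving
    smooth, tube-like dispersion rather than white noise.
    """
    center = centerline_points(spec)
    n1, n2 = _frames(center)
    npts = len(center)
    s = np.linspace(0.0, 1.0, npts)
    rng = np.random.default_rng(spec.seed)
    streamlines = []
    for _ in range(spec.n_streamlines):
        u0, v0 = rng.normal(0.0, spec.tube_sd, size=2)
        au, av = rng.normal(0.0, 0.3 * spec.tube_sd, size=2)
        fu, fv = rng.integers(1, 3, size=2)
        pu, pv = rng.uniform(0.0, 2 * np.pi, size=2)
        u = u0 + au * np.cos(2 * np.pi * fu * s + pu)
        v = v0 + av * np.cos(2 * np.pi * fv * s + pv)
        streamlines.append(center + u[:, None] * n1 + v[:, None] * n2)
    return Tractogram(streamlines)


def generate_branched_bundle(
    spec: BundleSpec,
    branch_fraction: float = 0.2,
    branch_offset: Sequence[float] = (0.0, 30.0, 0.0),
) -> tuple[Tractogram, np.ndarray]:
    """A bundle where a fraction of streamlines diverge to a side lobe.

    Branch streamlines follow the main tube over their first half, then
    ramp smoothly toward ``branch_offset`` so their terminal endpoints
    form a separate cluster.  Returns the tractogram and a boolean
    core-streamline label array (ground truth for trunk/branch tests).
    """
    t = generate_bundle(spec)
    rng = np.random.default_rng(spec.seed + 1)
    n = t.n_streamlines
    n_branch = int(round(branch_fraction * n))
    branch_idx = rng.choice(n, size=n_branch, replace=False)
    core = np.ones(n, dtype=bool)
    core[branch_idx] = False
    offset = np.asarray(branch_offset, dtype=float)
    out = []
    for i, s in enumerate(t.streamlines):
        if core[i]:
            out.append(s)
            continue
        npts = len(s)
        u = np.linspace(0.0, 1.0, npts)
        ramp = np.clip((u - 0.5) / 0.5, 0.0, 1.0)
        ramp = ramp * ramp * (3 - 2 * ramp)  # smoothstep
        out.append(s + ramp[:, None] * offset)
    return Tractogram(out), core


def perturb_bundle(t: Tractogram, p: PerturbationSpec) -> Tractogram:
    """Apply one perturbation model; deterministic given ``p.seed``.

    ``resample`` is a grid-level effect and leaves streamlines
    untouched (the study simulator voxelizes such datasets on their
    native grid instead).
    """
    rng = np.random.default_rng(p.seed)
    if p.model == "jitter":
        sd = float(p.magnitude)
        shifts = rng.normal(0.0, sd, size=(t.n_streamlines, 3))
        sl = [s + shift for s, shift in zip(t.streamlines, shifts)]
    elif p.model == "dropout":
        frac = float(p.magnitude)
        keep = rng.random(t.n_streamlines) >= frac
        if not keep.any():
            raise ValueError("dropout removed every streamline")
        sl = [s for s, k in zip(t.streamlines, keep) if k]
    elif p.model == "affine":
        mat = np.asarray(p.magnitude, dtype=float)
        if mat.shape != (4, 4):
            raise ValueError("affine perturbation needs a 4x4 matrix")
        sl = [s @ mat[:3, :3].T + mat[:3, 3] for s in t.streamlines]
    elif p.model == "radius_scale":
        scale = float(p.magnitude)
        lens = {len(s) for s in t.streamlines}
        if len(lens) != 1:
            raise ValueError("radius_scale requires equal-length streamlines")
        stack = np.stack(t.streamlines)
        center = stack.mean(axis=0)  # pointwise mean centerline
        sl = list(center + scale * (stack - center))
    else:  # resample
        sl = [s.copy() for s in t.streamlines]
    return Tractogram(
        sl, reference_affine=t.reference_affine, reference_shape=t.reference_shape
    )


# ---------------------------------------------------------------------------
# DWI simulation

def fibonacci_directions(n: int) -> np.ndarray:
    """Quasi-uniform unit vectors on the half-sphere (deterministic)."""
    i = np.arange(n) + 0.5
    phi = np.pi * (1.0 + np.sqrt(5.0)) * i
    z = i / n  # upper half-sphere
    r = np.sqrt(1.0 - z**2)
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def default_scheme(n_directions: int = 32, bval: float = 1000.0) -> DWIScheme:
    """One b0 plus ``n_directions`` DW volumes at ``bval`` s/mm²."""
    bvals = np.concatenate([[0.0], np.full(n_directions, bval)])
    bvecs = np.vstack([[0.0, 0.0, 0.0], fibonacci_directions(n_directions)])
    return DWIScheme(bvals, bvecs)


def simulate_dwi(
    tensor_field: np.ndarray,
    scheme: DWIScheme,
    snr: Optional[float] = 30.0,
    seed: int = 0,
    s0: float = 100.0,
) -> np.ndarray:
    """Single-tensor DWI signal with Rician noise.

    ``tensor_field`` is (..., 3, 3) in mm²/s; the noise level is
    ``s0 / snr`` per channel (``snr=None`` disables noise, giving the
    exact exponential decay model).
    """
    b = scheme.bvals
    g = scheme.bvecs
    # quadratic form b * g^T D g per voxel and volume
    quad = np.einsum("mi,...ij,mj->...m", g, tensor_field, g)
    signal = s0 * np.exp(-b * quad)
    if snr is None or not np.isfinite(snr):
        return signal
    if snr <= 0:
        raise ValueError("snr must be positive")
    rng = np.random.default_rng(seed)
    sigma = s0 / snr
    n1 = rng.normal(0.0, sigma, size=signal.shape)
    n2 = rng.normal(0.0, sigma, size=signal.shape)
    return np.sqrt((signal + n1) ** 2 + n2**2)


def linear_fa_tensor_field(
    shape: tuple[int, int, int],
    fa_axis: int = 2,
    lam_high: tuple[float, float, float] = (1.7e-3, 0.3e-3, 0.3e-3),
    lam_low: tuple[float, float, float] = (1.4e-3, 0.9e-3, 0.9e-3),
) -> np.ndarray:
    """Axis-aligned tensor field whose anisotropy ramps along one axis.

    Interpolates the eigenvalue triple from ``lam_low`` (low anisotropy,
    higher diffusivity) to ``lam_high`` (anisotropic, lower diffusivity)
    linearly along ``fa_axis``, so both FA and MD carry a spatial
    gradient and ROI displacement changes the in-bundle mean.
    """
    n = shape[fa_axis]
    w = np.arange(n) / max(n - 1, 1)
    field = np.zeros(shape + (3, 3))
    lam_low = np.asarray(lam_low)
    lam_high = np.asarray(lam_high)
    for k in range(n):
        lam = lam_low + w[k] * (lam_high - lam_low)
        sl = [slice(None)] * 3
        sl[fa_axis] = k
        field[tuple(sl)] = np.diag(lam)
    return field


# ---------------------------------------------------------------------------
# whole-study simulation

def _study_grid(all_points: np.ndarray, margin: float = 8.0, spacing: float = 1.0) -> GridSpec:
    lo = all_points.min(axis=0) - margin
    hi = all_points.max(axis=0) + margin
    shape = tuple(int(np.ceil((h - l) / spacing)) for l, h in zip(lo, hi))
    aff = np.eye(4)
    aff[:3, :3] *= spacing
    aff[:3, 3] = lo + spacing / 2.0
    return GridSpec(aff, shape)


def simulate_study(
    out_dir: str,
    n_subjects: int = 5,
    pathways: Optional[dict[str, BundleSpec]] = None,
    plan: Optional[dict[str, StudyCondition]] = None,
    seed: int = 0,
    with_dwi: bool = True,
    snr: float = 30.0,
    dwi_spacing: float = 2.5,
    n_directions: int = 32,
) -> StudyManifest:
    """Write a complete synthetic study (TRK + NIfTI + manifest) to disk.

    Per subject a reference dataset plus one perturbed dataset per
    confound in ``plan`` are produced; subject geometry varies slightly
    (bundle size ±10%) around the nominal pathway specs.  Ground truth
    (specs, plan, seeds) is stored as ``truth.json``.  Returns the
    parsed manifest.
    """
    if pathways is None:
        pathways = {
            "ARC": BundleSpec(kind="arc", radius=30.0, angle_deg=180.0),
            "STRAIGHT": BundleSpec(kind="straight", length=60.0, origin=(0.0, -20.0, 10.0)),
        }
    if plan is None:
        plan = default_confound_plan()
    os.makedirs(os.path.join(out_dir, "bundles"), exist_ok=True)
    if with_dwi:
        os.makedirs(os.path.join(out_dir, "dwi"), exist_ok=True)

    root_ss = np.random.SeedSequence(seed)
    subjects = [f"sub{i+1:02d}" for i in range(n_subjects)]
    datasets = ["ref"] + [c.lower() for c in plan]
    confound_of = {c.lower(): c for c in plan}

    # generate all tractograms first so a single study grid can be derived
    tractos: dict[tuple[str, str, str], Tractogram] = {}
    sub_seeds = root_ss.spawn(n_subjects)
    for subject, ss in zip(subjects, sub_seeds):
        rng = np.random.default_rng(ss)
        scale = 1.0 + rng.uniform(-0.1, 0.1)
        for pathway, spec0 in pathways.items():
            spec = replace(
                spec0,
                radius=spec0.radius * scale,
                length=spec0.length * scale,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            ref = generate_bundle(spec)
            tractos[(subject, "ref", pathway)] = ref
            for confound, cond in plan.items():
                t = ref
                for p in cond.perturbations:
                    t = perturb_bundle(
                        t, replace(p, seed=int(rng.integers(0, 2**31 - 1)))
                    )
                tractos[(subject, confound.lower(), pathway)] = t

    all_pts = np.vstack([np.vstack(t.streamlines) for t in tractos.values()])
    grid = _study_grid(all_pts)
    write_volume(Volume(np.zeros(grid.shape), grid.affine), os.path.join(out_dir, "grid.nii.gz"))

    for (subject, dataset, pathway), t in tractos.items():
        t = Tractogram(t.streamlines, reference_affine=grid.affine, reference_shape=grid.shape)
        write_tractogram(
            t, os.path.join(out_dir, "bundles", f"{subject}_{dataset}_{pathway}.trk")
        )

    manifest_datasets: dict[str, dict] = {}
    for dataset in datasets:
        entry: dict = {"bundles": "bundles/{subject}_{dataset}_{pathway}.trk"}
        cond = plan.get(confound_of.get(dataset, ""), None)
        if cond is not None and cond.voxel_size is not None:
            entry["voxel_size"] = float(cond.voxel_size)
        if with_dwi:
            entry["dwi"] = "dwi/{subject}_{dataset}.nii.gz"
            entry["bval"] = "dwi/{subject}_{dataset}.bval"
            entry["bvec"] = "dwi/{subject}_{dataset}.bvec"
        manifest_datasets[dataset] = entry

    if with_dwi:
        scheme = default_scheme(n_directions=n_directions)
        dwi_shape = tuple(
            max(int(np.ceil(n * 1.0 / dwi_spacing)), 4) for n in grid.shape
        )
        dwi_aff = np.eye(4)
        dwi_aff[:3, :3] *= dwi_spacing
        dwi_aff[:3, 3] = grid.affine[:3, 3] - grid.affine[:3, :3] @ np.full(3, 0.5) + dwi_spacing / 2.0
        field = linear_fa_tensor_field(dwi_shape, fa_axis=1)
        noise_ss = root_ss.spawn(1)[0]
        nrng = np.random.default_rng(noise_ss)
        for subject in subjects:
            for dataset in datasets:
                data = simulate_dwi(
                    field, scheme, snr=snr, seed=int(nrng.integers(0, 2**31 - 1))
                )
                base = os.path.join(out_dir, "dwi", f"{subject}_{dataset}")
                write_dwi(data, dwi_aff, base + ".nii.gz")
                write_bvals_bvecs(scheme.bvals, scheme.bvecs, base + ".bval", base + ".bvec")

    manifest = StudyManifest(
        subjects=subjects,
        pathways=list(pathways),
        datasets=manifest_datasets,
        contrasts=[(c, "ref", c.lower()) for c in plan],
        reference_dataset="ref",
        grid="grid.nii.gz",
        root=os.path.abspath(out_dir),
    )
    write_manifest(manifest, os.path.join(out_dir, "manifest.yaml"))
    truth = {
        "seed": seed,
        "n_subjects": n_subjects,
        "pathways": {k: vars(v).copy() for k, v in pathways.items()},
        "plan": {
            c: {
                "voxel_size": cond.voxel_size,
                "perturbations": [
                    {"model": p.model, "magnitude": np.asarray(p.magnitude).tolist()}
                    for p in cond.perturbations
                ],
            }
            for c, cond in plan.items()
        },
    }
    with open(os.path.join(out_dir, "truth.json"), "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
    return manifest
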