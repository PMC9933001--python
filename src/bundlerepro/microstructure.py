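"""Diffusion-tensor fitting and in-bundle FA/MD extraction.

The tensor is estimated per voxel by iteratively reweighted linear
least squares (IRWLLS): an ordinary log-linear fit followed by N
weighted refits with weights equal to the squared predicted signal —
the standard correction for the log transform's heteroscedasticity.
FA and MD come from the eigenvalues (clamped at zero):

    MD = (λ1 + λ2 + λ3) / 3
    FA = sqrt(3/2 · Σ(λi − MD)² / Σλi²)

In-bundle means are extracted in two ROI modes: a fixed reference-scan
ROI (isolating the acquisition confound while holding the ROI constant)
and each dataset's own native ROI (adding tractography variability);
the gap between the two MAPEs is the variance added by tractography.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .repro_stats import mape
from .voxelization import BundleMask

B0_THRESHOLD = 50.0  # s/mm²: volumes with b <= 50 count as non-DW


class TensorFitError(ValueError):
    """Fewer usable volumes than unknowns, or a singular design."""


@dataclass
class DWIScheme:
    """Gradient scheme: b-values (s/mm²) and unit gradient directions."""

    bvals: np.ndarray
    bvecs: np.ndarray

    def __post_init__(self) -> None:
        self.bvals = np.asarray(self.bvals, dtype=float).ravel()
        self.bvecs = np.asarray(self.bvecs, dtype=float)
        if self.bvecs.shape != (len(self.bvals), 3):
            raise ValueError("bvecs must be (n_volumes, 3)")
        dw = self.bvals > B0_THRESHOLD
        if dw.sum() < 6 or (~dw).sum() < 1:
            raise ValueError("scheme needs >= 1 b0 and >= 6 DW volumes")
        norms = np.linalg.norm(self.bvecs[dw], axis=1)
        if not np.allclose(norms, 1.0, atol=1e-3):
            raise ValueError("DW gradient directions must have unit norm")

    @property
    def n_volumes(self) -> int:
        return len(self.bvals)

    def design_matrix(self) -> np.ndarray:
        """Rows (1, −b gx², −b gy², −b gz², −2b gx gy, −2b gx gz, −2b gy gz)."""
        b = self.bvals
        gx, gy, gz = self.bvecs.T
        return np.column_stack(
            [
                np.ones_like(b),
                -b * gx**2,
                -b * gy**2,
                -b * gz**2,
                -2 * b * gx * gy,
                -2 * b * gx * gz,
                -2 * b * gy * gz,
            ]
        )


@dataclass
class TensorFit:
    """Voxelwise tensor fit results on the DWI grid."""

    tensor: np.ndarray  # (..., 3, 3) in mm²/s
    s0: np.ndarray
    fa: np.ndarray
    md: np.ndarray
    affine: np.ndarray
    n_excluded_voxels: int = 0


def _theta_to_tensor(theta: np.ndarray) -> np.ndarray:
    """(V, 7) parameters → (V, 3, 3) symmetric tensors."""
    dxx, dyy, dzz, dxy, dxz, dyz = theta[:, 1], theta[:, 2], theta[:, 3], theta[:, 4], theta[:, 5], theta[:, 6]
    T = np.empty((len(theta), 3, 3))
    T[:, 0, 0], T[:, 1, 1], T[:, 2, 2] = dxx, dyy, dzz
    T[:, 0, 1] = T[:, 1, 0] = dxy
    T[:, 0, 2] = T[:, 2, 0] = dxz
    T[:, 1, 2] = T[:, 2, 1] = dyz
    return T


def fa_md_from_eigenvalues(evals: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """FA and MD from (V, 3) eigenvalues, negatives clamped to zero."""
    lam = np.clip(evals, 0.0, None)
    md = lam.mean(axis=-1)
    num = ((lam - md[..., None]) ** 2).sum(axis=-1)
    den = (lam**2).sum(axis=-1)
    fa = np.zeros_like(md)
    nz = den > 0
    fa[nz] = np.sqrt(1.5 * num[nz] / den[nz])
    return np.clip(fa, 0.0, 1.0), md


def _wls_solve(B: np.ndarray, y: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Batched weighted LS: argmin_θ Σ w (y − Bθ)², y/w shaped (V, m)."""
    A = np.einsum("mi,vm,mj->vij", B, w, B)
    rhs = np.einsum("mi,vm->vi", B, w * y)
    return np.linalg.solve(A, rhs[..., None])[..., 0]


def fit_tensor_irwlls(
    dwi: np.ndarray,
    scheme: DWIScheme,
    mask: Optional[np.ndarray] = None,
    affine: Optional[np.ndarray] = None,
    n_iter: int = 2,
) -> TensorFit:
    """IRWLLS tensor fit over masked voxels of a 4-D DWI array.

    Non-positive signals are excluded per voxel (log undefined); voxels
    retaining fewer than 7 usable volumes are excluded from the fit and
    counted in ``n_excluded_voxels``.  ``n_iter`` reweighting passes
    follow the initial unweighted log-linear solve; ``n_iter=0``
    reproduces ordinary log-linear least squares.
    """
    dwi = np.asarray(dwi, dtype=float)
    if dwi.ndim != 4:
        raise ValueError("dwi must be 4-D (x, y, z, volumes)")
    if dwi.shape[-1] != scheme.n_volumes:
        raise ValueError("volume count does not match the gradient scheme")
    spatial = dwi.shape[:3]
    if mask is None:
        mask = np.ones(spatial, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    B = scheme.design_matrix()
    if np.linalg.matrix_rank(B) < 7:
        raise TensorFitError("singular design matrix: need 7 independent volumes")

    vox = np.argwhere(mask)
    signals = dwi[mask]  # (V, m)
    theta = np.full((len(vox), 7), np.nan)
    pos = signals > 0
    clean = pos.all(axis=1)
    n_excluded = 0

    def irwlls(Bv: np.ndarray, yv: np.ndarray) -> np.ndarray:
        # yv: (V, m) log-signals for a shared design Bv
        th = np.linalg.lstsq(Bv, yv.T, rcond=None)[0].T
        for _ in range(n_iter):
            w = np.exp(2.0 * (th @ Bv.T))  # squared predicted signal
            th = _wls_solve(Bv, yv, w)
        return th

    if clean.any():
        theta[clean] = irwlls(B, np.log(signals[clean]))
    for i in np.nonzero(~clean)[0]:
        use = pos[i]
        if use.sum() < 7 or np.linalg.matrix_rank(B[use]) < 7:
            n_excluded += 1
            continue
        theta[i] = irwlls(B[use], np.log(signals[i, use])[None, :])[0]

    fitted = ~np.isnan(theta[:, 0])
    tensors = np.zeros(spatial + (3, 3))
    s0 = np.zeros(spatial)
    fa = np.zeros(spatial)
    md = np.zeros(spatial)
    if fitted.any():
        T = _theta_to_tensor(theta[fitted])
        evals = np.linalg.eigvalsh(T)
        fa_v, md_v = fa_md_from_eigenvalues(evals)
        ij = vox[fitted]
        tensors[ij[:, 0], ij[:, 1], ij[:, 2]] = T
        s0[ij[:, 0], ij[:, 1], ij[:, 2]] = np.exp(theta[fitted, 0])
        fa[ij[:, 0], ij[:, 1], ij[:, 2]] = fa_v
        md[ij[:, 0], ij[:, 1], ij[:, 2]] = md_v
    return TensorFit(
        tensor=tensors,
        s0=s0,
        fa=fa,
        md=md,
        affine=np.eye(4) if affine is None else np.asarray(affine, dtype=float),
        n_excluded_voxels=n_excluded,
    )


def extract_in_bundle(metric: np.ndarray, roi: BundleMask | np.ndarray) -> tuple[float, int]:
    """Arithmetic mean of a metric map over an ROI; returns (mean, n_voxels)."""
    roi_arr = roi.mask if isinstance(roi, BundleMask) else np.asarray(roi, dtype=bool)
    metric = np.asarray(metric)
    if metric.shape != roi_arr.shape:
        raise ValueError("metric and ROI must share a grid")
    n = int(roi_arr.sum())
    if n == 0:
        raise ValueError("empty ROI: in-bundle mean is undefined")
    return float(metric[roi_arr].mean()), n


def variance_decomposition(
    metric_maps: Mapping[str, np.ndarray],
    native_rois: Mapping[str, BundleMask | np.ndarray],
    reference_roi: BundleMask | np.ndarray,
    contrasts: Iterable[tuple[str, str, str]],
) -> pd.DataFrame:
    """Fixed-ROI vs native-ROI MAPE of in-bundle means, per contrast.

    ``mape_fixed_roi`` extracts both datasets' maps with the single
    reference ROI (source-of-variation only); ``mape_native_roi`` uses
    each dataset's own ROI, which adds tractography variability.
    Contrasts with a missing map or ROI are skipped.
    """
    rows = []
    for confound, da, db in contrasts:
        if da not in metric_maps or db not in metric_maps:
            continue
        if da not in native_rois or db not in native_rois:
            continue
        fixed_a, _ = extract_in_bundle(metric_maps[da], reference_roi)
        fixed_b, _ = extract_in_bundle(metric_maps[db], reference_roi)
        native_a, _ = extract_in_bundle(metric_maps[da], native_rois[da])
        native_b, _ = extract_in_bundle(metric_maps[db], native_rois[db])
        rows.append(
            {
                "confound": confound,
                "dataset_a": da,
                "dataset_b": db,
                "mape_fixed_roi": mape(fixed_a, fixed_b),
                "mape_native_roi": mape(native_a, native_b),
            }
        )
    return pd.DataFrame(rows, columns=["confound", "dataset_a", "dataset_b", "mape_fixed_roi", "mape_native_roi"])
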