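"""End-to-end study orchestration.

``run_study`` drives the full analysis from a manifest: voxelize every
bundle to a standardized 1 mm mask on the study grid, apply streamline
QC, compute pairwise Dice per contrast, the 12 shape features and their
paired MAPE/MPV, confound-vs-confound Wilcoxon comparisons, voxelwise
agreement maps, and the fixed- vs native-ROI FA/MD decomposition when
DWI data are present.  Stages communicate through files in a structured
output tree so a run is inspectable and re-runnable.
"""
from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from ._grids import GridSpec, isotropic_grid_like
from .io_bundles import (
    EmptyTractogramError,
    StudyManifest,
    Volume,
    read_bvals_bvecs,
    read_dwi,
    read_manifest,
    read_tractogram,
    read_volume,
    write_volume,
)
from .microstructure import (
    DWIScheme,
    extract_in_bundle,
    fit_tensor_irwlls,
    variance_decomposition,
)
from .overlap_maps import agreement_map, dice
from .repro_stats import (
    DEFAULT_ALPHA,
    QC_MIN_STREAMLINES,
    QC_SD_FACTOR,
    QC_SUBJECT_FRACTION,
    QCReport,
    mape,
    mpv,
    paired_wilcoxon,
    qc_filter,
)
from .shape_features import FEATURE_NAMES, compute_shape_features
from .voxelization import BundleMask, density_to_mask, standardize_mask, streamlines_to_density

log = logging.getLogger("bundlerepro")

_CSV_FLOAT = "%.10g"


@dataclass
class RunConfig:
    """Thresholds and paths of one pipeline run."""

    manifest: str
    out_dir: str
    density_threshold: int = 1
    probability_threshold: float = 2.5e-4
    qc_min_streamlines: int = QC_MIN_STREAMLINES
    qc_sd_factor: float = QC_SD_FACTOR
    qc_subject_fraction: float = QC_SUBJECT_FRACTION
    alpha: float = DEFAULT_ALPHA
    seed: int = 0
    write_maps: bool = True

    def __post_init__(self) -> None:
        if self.density_threshold < 1 or self.probability_threshold <= 0:
            raise ValueError("thresholds must be positive")
        if not (0.0 < self.qc_subject_fraction < 1.0):
            raise ValueError("qc_subject_fraction must be in (0, 1)")


@dataclass
class ResultsBundle:
    dice_table: pd.DataFrame
    shape_table: pd.DataFrame
    mape_table: pd.DataFrame
    dice_wilcoxon: Optional[object]
    micro_table: pd.DataFrame
    qc: QCReport
    masks: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)


def _study_grid(m: StudyManifest) -> GridSpec:
    if m.grid is None:
        raise ValueError("manifest must declare a study grid image")
    vol = read_volume(os.path.join(m.root, m.grid))
    grid = GridSpec(vol.affine, tuple(vol.data.shape))
    if not np.allclose(grid.voxel_sizes, 1.0, atol=1e-6):
        grid = isotropic_grid_like(grid.affine, grid.shape, spacing=1.0)
    return grid


def _native_grid(grid_1mm: GridSpec, voxel_size: float) -> GridSpec:
    aff = grid_1mm.affine.copy()
    vs = np.linalg.norm(aff[:3, :3], axis=0)
    dirs = aff[:3, :3] / vs
    corner = aff[:3, 3] - aff[:3, :3] @ np.full(3, 0.5)
    shape = tuple(int(np.ceil(n / voxel_size)) for n in grid_1mm.shape)
    new = np.eye(4)
    new[:3, :3] = dirs * voxel_size
    new[:3, 3] = corner + new[:3, :3] @ np.full(3, 0.5)
    return GridSpec(new, shape)


def voxelize_bundle(
    t, grid_1mm: GridSpec, voxel_size: Optional[float], density_threshold: int
) -> BundleMask:
    """Density-1 mask on the 1 mm study grid, via the native grid if any."""
    if voxel_size is None or abs(voxel_size - 1.0) < 1e-9:
        d = streamlines_to_density(t, grid_1mm.affine, grid_1mm.shape)
        return density_to_mask(d, density_threshold, target=grid_1mm)
    native = _native_grid(grid_1mm, voxel_size)
    d = streamlines_to_density(t, native.affine, native.shape)
    return density_to_mask(d, density_threshold, target=grid_1mm)


def run_study(cfg: RunConfig) -> ResultsBundle:
    """Execute every stage; per-bundle failures are logged, not fatal."""
    manifest = read_manifest(cfg.manifest)
    out = cfg.out_dir
    os.makedirs(out, exist_ok=True)
    grid = _study_grid(manifest)

    # ---- load + voxelize ---------------------------------------------
    masks: dict[tuple[str, str, str], BundleMask] = {}
    tractos: dict[tuple[str, str, str], object] = {}
    count_rows = []
    failures = []
    for subject in manifest.subjects:
        for dataset in manifest.datasets:
            vs = manifest.datasets[dataset].get("voxel_size")
            for pathway in manifest.pathways:
                path = manifest.bundle_path(dataset, subject, pathway)
                key = (subject, dataset, pathway)
                try:
                    t = read_tractogram(path)
                except FileNotFoundError:
                    failures.append((*key, "missing file"))
                    continue
                except EmptyTractogramError:
                    count_rows.append(
                        {"subject": subject, "dataset": dataset, "pathway": pathway, "n_streamlines": 0}
                    )
                    continue
                tractos[key] = t
                count_rows.append(
                    {"subject": subject, "dataset": dataset, "pathway": pathway, "n_streamlines": t.n_streamlines}
                )
                masks[key] = voxelize_bundle(t, grid, vs, cfg.density_threshold)
    counts = pd.DataFrame(count_rows)

    # ---- QC -----------------------------------------------------------
    qc = qc_filter(
        counts,
        min_streamlines=cfg.qc_min_streamlines,
        sd_factor=cfg.qc_sd_factor,
        subject_fraction=cfg.qc_subject_fraction,
    )
    for s, d, p, reason in failures:
        qc.removed_bundles.append((s, d, p, reason))
    removed = {(s, d, p) for s, d, p, _ in qc.removed_bundles}
    removed_subj = {s for s, _, _ in qc.removed_subjects}

    def ok(subject, dataset, pathway):
        return (
            subject not in removed_subj
            and (subject, dataset, pathway) not in removed
            and (subject, dataset, pathway) in masks
        )

    # ---- Dice per contrast -------------------------------------------
    dice_rows = []
    for confound, da, db in manifest.contrasts:
        for subject in manifest.subjects:
            for pathway in manifest.pathways:
                if not (ok(subject, da, pathway) and ok(subject, db, pathway)):
                    continue
                r = dice(masks[(subject, da, pathway)], masks[(subject, db, pathway)])
                if r.undefined:
                    qc.removed_bundles.append((subject, f"{da}|{db}", pathway, "both masks empty"))
                    continue
                dice_rows.append(
                    {
                        "subject": subject,
                        "pathway": pathway,
                        "contrast": confound,
                        "dice": r.dice,
                        "vol_a": r.vol_a,
                        "vol_b": r.vol_b,
                        "intersection": r.intersection,
                    }
                )
    dice_table = pd.DataFrame(
        dice_rows, columns=["subject", "pathway", "contrast", "dice", "vol_a", "vol_b", "intersection"]
    )

    # ---- shape features ----------------------------------------------
    shape_rows = []
    for (subject, dataset, pathway), t in sorted(tractos.items()):
        if not ok(subject, dataset, pathway) or masks[(subject, dataset, pathway)].empty:
            continue
        try:
            feats = compute_shape_features(t, masks[(subject, dataset, pathway)])
        except Exception as exc:  # degenerate bundles are skipped, not fatal
            log.warning("shape features failed for %s/%s/%s: %s", subject, dataset, pathway, exc)
            continue
        shape_rows.append(
            {"subject": subject, "dataset": dataset, "pathway": pathway, **feats.as_dict()}
        )
    shape_table = pd.DataFrame(
        shape_rows, columns=["subject", "dataset", "pathway", *FEATURE_NAMES]
    )

    # ---- paired MAPE / MPV -------------------------------------------
    mape_rows = []
    if not shape_table.empty:
        indexed = shape_table.set_index(["subject", "dataset", "pathway"])
        for confound, da, db in manifest.contrasts:
            for subject in manifest.subjects:
                for pathway in manifest.pathways:
                    try:
                        ra = indexed.loc[(subject, da, pathway)]
                        rb = indexed.loc[(subject, db, pathway)]
                    except KeyError:
                        continue
                    for feat in FEATURE_NAMES:
                        a, b = float(ra[feat]), float(rb[feat])
                        if (a + b) == 0:
                            continue
                        mape_rows.append(
                            {
                                "subject": subject,
                                "pathway": pathway,
                                "contrast": confound,
                                "feature": feat,
                                "mape": mape(a, b),
                                "mpv": mpv(a, b),
                            }
                        )
    mape_table = pd.DataFrame(
        mape_rows, columns=["subject", "pathway", "contrast", "feature", "mape", "mpv"]
    )

    # ---- Wilcoxon across confounds on Dice ---------------------------
    dice_wilcoxon = None
    if not dice_table.empty and dice_table["contrast"].nunique() >= 2:
        per_subject = dice_table.groupby(["contrast", "subject"])["dice"].mean()
        groups = {c: per_subject.loc[c] for c in per_subject.index.get_level_values(0).unique()}
        dice_wilcoxon = paired_wilcoxon(groups, alpha=cfg.alpha)

    # ---- agreement maps ----------------------------------------------
    if cfg.write_maps:
        maps_dir = os.path.join(out, "maps")
        os.makedirs(maps_dir, exist_ok=True)
        for confound, da, db in manifest.contrasts:
            for pathway in manifest.pathways:
                pairs = [
                    (masks[(s, da, pathway)], masks[(s, db, pathway)])
                    for s in manifest.subjects
                    if ok(s, da, pathway) and ok(s, db, pathway)
                ]
                if not pairs:
                    continue
                am = agreement_map(pairs)
                write_volume(
                    Volume(am.agree_frac, am.affine),
                    os.path.join(maps_dir, f"{pathway}_{confound}_agree.nii.gz"),
                )
                write_volume(
                    Volume(am.disagree_frac, am.affine),
                    os.path.join(maps_dir, f"{pathway}_{confound}_disagree.nii.gz"),
                )

    # ---- microstructure ----------------------------------------------
    micro_rows = []
    has_dwi = any("dwi" in manifest.datasets[d] for d in manifest.datasets)
    if has_dwi:
        for subject in manifest.subjects:
            if subject in removed_subj:
                continue
            fa_maps, md_maps, dwi_grid = {}, {}, None
            for dataset in manifest.datasets:
                paths = manifest.dwi_paths(dataset, subject)
                if paths is None:
                    continue
                try:
                    data, affine = read_dwi(paths["dwi"])
                    bvals, bvecs = read_bvals_bvecs(paths["bval"], paths["bvec"])
                except FileNotFoundError:
                    log.warning("missing DWI for %s/%s", subject, dataset)
                    continue
                fit = fit_tensor_irwlls(data, DWIScheme(bvals, bvecs), affine=affine)
                fa_maps[dataset] = fit.fa
                md_maps[dataset] = fit.md
                dwi_grid = GridSpec(affine, data.shape[:3])
            if dwi_grid is None:
                continue
            for pathway in manifest.pathways:
                rois = {
                    d: standardize_mask(masks[(subject, d, pathway)], dwi_grid)
                    for d in manifest.datasets
                    if ok(subject, d, pathway) and not masks[(subject, d, pathway)].empty
                }
                ref = manifest.reference_dataset
                if ref not in rois or rois[ref].empty:
                    log.warning("missing reference ROI for %s/%s; contrasts skipped", subject, pathway)
                    continue
                rois = {d: r for d, r in rois.items() if not r.empty}
                for metric_name, maps in (("fa", fa_maps), ("md", md_maps)):
                    vd = variance_decomposition(maps, rois, rois[ref], manifest.contrasts)
                    for _, row in vd.iterrows():
                        micro_rows.append(
                            {"subject": subject, "pathway": pathway, "metric": metric_name, **row.to_dict()}
                        )
    micro_table = pd.DataFrame(
        micro_rows,
        columns=["subject", "pathway", "metric", "confound", "dataset_a", "dataset_b", "mape_fixed_roi", "mape_native_roi"],
    )

    # ---- write outputs ------------------------------------------------
    dice_table.to_csv(os.path.join(out, "dice.csv"), index=False, float_format=_CSV_FLOAT)
    shape_table.to_csv(os.path.join(out, "shape.csv"), index=False, float_format=_CSV_FLOAT)
    mape_table.to_csv(os.path.join(out, "shape_mape.csv"), index=False, float_format=_CSV_FLOAT)
    micro_table.to_csv(os.path.join(out, "micro_mape.csv"), index=False, float_format=_CSV_FLOAT)
    counts.to_csv(os.path.join(out, "streamline_counts.csv"), index=False, float_format=_CSV_FLOAT)
    if dice_wilcoxon is not None:
        dice_wilcoxon.p_values.to_csv(os.path.join(out, "wilcoxon_dice_p.csv"), float_format=_CSV_FLOAT)
    with open(os.path.join(out, "qc_report.json"), "w") as fh:
        json.dump(
            {
                "removed_bundles": [list(x) for x in qc.removed_bundles],
                "removed_subjects": [list(x) for x in qc.removed_subjects],
            },
            fh,
            indent=1,
            sort_keys=True,
        )
    provenance = {
        "config": {
            k: v for k, v in vars(cfg).items() if isinstance(v, (int, float, str, bool))
        },
        "n_bundles": len(masks),
        "grid_shape": list(grid.shape),
    }
    provenance["config_hash"] = hashlib.sha256(
        json.dumps(provenance["config"], sort_keys=True).encode()
    ).hexdigest()[:16]
    with open(os.path.join(out, "provenance.json"), "w") as fh:
        json.dump(provenance, fh, indent=1, sort_keys=True)

    results = ResultsBundle(
        dice_table=dice_table,
        shape_table=shape_table,
        mape_table=mape_table,
        dice_wilcoxon=dice_wilcoxon,
        micro_table=micro_table,
        qc=qc,
        masks=masks,
        provenance=provenance,
    )
    summary = summarize(results)
    for name, tab in summary.items():
        tab.to_csv(os.path.join(out, f"summary_{name}.csv"), index=False, float_format=_CSV_FLOAT)
    return results


def summarize(r: ResultsBundle) -> dict[str, pd.DataFrame]:
    """Per-confound Dice medians/IQRs and per-feature mean-MAPE ordering."""
    if r.dice_table.empty and r.mape_table.empty:
        raise ValueError("cannot summarize empty results")
    out: dict[str, pd.DataFrame] = {}
    if not r.dice_table.empty:
        g = r.dice_table.groupby("contrast")["dice"]
        out["dice_by_confound"] = (
            pd.DataFrame(
                {
                    "contrast": g.median().index,
                    "median_dice": g.median().values,
                    "iqr_low": g.quantile(0.25).values,
                    "iqr_high": g.quantile(0.75).values,
                    "mean_dice": g.mean().values,
                    "n": g.size().values,
                }
            )
            .sort_values(["median_dice", "contrast"], ascending=[False, True], kind="mergesort")
            .reset_index(drop=True)
        )
    if not r.mape_table.empty:
        g = r.mape_table.groupby("feature")["mape"]
        ordering = (
            pd.DataFrame({"feature": g.mean().index, "mean_mape": g.mean().values, "median_mape": g.median().values})
            .sort_values(["mean_mape", "feature"], kind="mergesort")
            .reset_index(drop=True)
        )
        out["feature_mape_ordering"] = ordering
        g2 = r.mape_table.groupby(["contrast", "feature"])["mape"].mean().reset_index()
        out["mape_by_confound_feature"] = g2
    if not r.micro_table.empty:
        g3 = (
            r.micro_table.groupby(["metric", "confound"])[["mape_fixed_roi", "mape_native_roi"]]
            .mean()
            .reset_index()
        )
        g3["added_by_tractography"] = g3["mape_native_roi"] - g3["mape_fixed_roi"]
        out["micro_by_confound"] = g3
    return out
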