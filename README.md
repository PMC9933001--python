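# bundlerepro

Reproducibility analysis for white-matter bundles reconstructed by
diffusion-MRI tractography.

When the same subject is scanned twice, on different scanners, from
different vendors, or with different spatial resolutions, diffusion
directions or b-values, the reconstructed fiber bundles (arcuate
fasciculus, corticospinal tract, …) differ. `bundlerepro` quantifies how
much, and where, for any study organized as paired "datasets" of the
same subjects:

- **Standardization** — streamline bundles (TRK/TCK) are binarized at a
  streamline density of 1 and resampled to 1 mm isotropic binary masks;
  probabilistic visitation maps are thresholded (default 2.5×10⁻⁴,
  inclusive). All comparisons happen on these masks.
- **Spatial reproducibility** — pairwise Dice overlap,
  Dice = 2|A∩B| / (|A|+|B|), plus voxelwise agreement/disagreement maps
  that localize where a bundle is consistently found across subjects.
- **Shape** — 12 geometry descriptors per bundle: mean length, span,
  equivalent-cylinder diameter, end-region radius, surface area,
  end-region area, total/trunk/branch volume, curl (length/span),
  elongation (length/diameter) and irregularity (surface area over the
  equivalent cylinder's lateral surface).
- **Paired statistics** — MAPE = 100·|x₁−x₂|/mean(x₁,x₂) for every
  matched pair, its signed version MPV (bias detection), and
  confound-vs-confound Wilcoxon signed-rank tests with Bonferroni
  correction over the comparisons actually run. QC removes bundles with
  < 200 streamlines or counts more than 3 SD below their pathway mean,
  and subjects with > 20 % failed pathways.
- **Microstructure** — diffusion-tensor fits by iteratively reweighted
  linear least squares (IRWLLS); in-bundle mean FA/MD extracted with a
  fixed reference-scan ROI (acquisition effect only) and with each
  dataset's native ROI (adds tractography variability); the gap between
  the two MAPEs is the variance added by tractography.
- **Synthetic studies** — a generator builds multi-dataset studies of
  tube-like bundles under controlled confounds (streamline jitter,
  dropout, affine, radius scaling, native-grid resolution change) and
  single-tensor DWI with Rician noise, so the whole pipeline runs with
  known ground truth and no data download.

## Worked example

```sh
bundlerepro simulate --out study --subjects 3 --seed 1 --small
bundlerepro run --manifest study/manifest.yaml --out analysis
```

which prints

```
wrote study with 3 subjects, 3 contrasts to study
analyzed 18 bundle pairs; 0 bundles failed QC; results in analysis
```

and `analysis/summary_dice_by_confound.csv` contains

```
contrast,median_dice,iqr_low,iqr_high,mean_dice,n
RESCAN,0.8595816013,0.8555929075,0.876496942,0.8585426171,6
SCAN,0.6276217582,0.6192521107,0.6330189785,0.6306746571,6
RES,0.3074832512,0.2988039208,0.3168160738,0.3092336885,6
```

Read: repeating a scan (RESCAN, mild jitter) leaves bundle masks highly
overlapping (median Dice ≈ 0.86); switching scanners (SCAN) costs more
(≈ 0.63); changing spatial resolution (RES, coarse native grid plus the
largest geometric displacement) is most disruptive (≈ 0.31) — the
severity ordering the synthetic confound plan encodes. `analysis/` also
holds the per-bundle Dice and shape tables, MAPE/MPV per contrast,
Wilcoxon p-value matrices, agreement/disagreement NIfTI maps, the
fixed- vs native-ROI FA/MD decomposition and the QC report. The same
API is available in Python via `bundlerepro.simulate_study`,
`bundlerepro.run_study` and friends.

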