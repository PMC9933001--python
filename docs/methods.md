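# Methods

This note documents the models, definitions and numerical choices behind
`bundlerepro`, in the order the pipeline applies them, and states what
the synthetic test bed does and does not demonstrate.

## Coordinate conventions and voxelization

All streamlines live internally in world RAS millimetres; TRK's
voxel-space dialect is converted on read. TCK headers carry no reference
grid, so TCK input receives an identity affine unless the caller
supplies a reference image. A world point belongs to the voxel whose
index is `round(inv(affine) @ x)`, with an exact .5 tie broken toward
the lower index — the same convention nearest-neighbor resampling uses,
so masks and tractograms agree about voxel ownership.

Streamline density maps count *distinct* streamlines per voxel: every
segment is walked at a sub-voxel step (default **0.1 mm**) and visits
are de-duplicated per streamline. The step is a speed/fidelity tradeoff:
a segment that clips a voxel's ownership cell for less than one step can
be missed, so runs that must agree bitwise with the 0.01 mm enumeration
oracle pass `step=0.01`. At the default step, the guaranteed property is
coverage: every streamline point lies within half a voxel of its
density-1 mask.

Masks are standardized to 1 mm isotropic grids by nearest-neighbor
resampling (never interpolate-then-threshold, which would break
binarity). Probability/visitation maps binarize at an inclusive
threshold, default 2.5×10⁻⁴. The density threshold default is 1.
Both-empty mask pairs yield an *undefined* Dice (flagged and routed to
QC), not zero: 0/0 carries no overlap information.

Agreement maps report, per voxel, the fraction of pairs where both
masks contain the voxel and where exactly one does, with the all-pairs
denominator (so agree + disagree + both-absent = 1 exactly); a
pairs-covering-the-voxel denominator would inflate disagreement in
rarely-visited voxels.

## Shape descriptors

Twelve descriptors per bundle. Streamlines are first co-oriented:
endpoints are split into two sides by the sign of their projection onto
the endpoint cloud's first principal axis, and each streamline is
flipped so its start is nearer side A's centroid. Then:

- **mean_length** — mean polyline arc length (mm).
- **span** — distance between the centroids of start and end points.
  Centroid-based span is robust to single outlier streamlines; an
  extreme-point definition would not be.
- **curl** = mean_length / span (1 for a straight bundle, π/2 for a
  semicircle).
- **volume** — 1 mm³ × voxel count of the standardized mask.
- **surface_area** — exposed voxel faces (6-connectivity) × 1 mm².
  Exact on voxel sets and oracle-checkable, unlike marching cubes.
  Note the systematic staircase effect: the digital lateral surface of
  a smooth cylinder exceeds π·d·L by ≈ 4/π, so a perfect r=5 mm,
  L=100 mm cylinder has irregularity ≈ 1.43 under these definitions,
  not 1. Comparisons between bundles measured the same way are
  unaffected.
- **diameter** = 2·√(volume / (π·mean_length)) — the cylinder of equal
  volume and length; **elongation** = mean_length / diameter;
  **irregularity** = surface_area / (π·diameter·mean_length).
- **end regions** — the mask-grid voxels containing at least one
  endpoint of each side; **end_area** sums both sides,
  **end_radius** averages the disc-equivalent radii √(area/π).
- **trunk/branch volume** — core streamlines are those whose both
  endpoints fall in the dominant endpoint cluster of their side
  (single-linkage at 10 mm, exposed as a parameter); the trunk is the
  density-1 mask of the core streamlines, branch volume is the rest.
  trunk + branch = volume by construction.

These formulas are this package's normative definitions; validation is
against closed-form phantoms (straight and semicircular bundles, digital
cylinders, cubes) and scale/rigid-motion equivariance, all within a 5 %
discretization tolerance at 1 mm.

## Paired statistics and QC

For a matched pair (x₁, x₂) of the same subject and pathway under two
conditions, MAPE = 100·|x₁−x₂| / mean(x₁,x₂) and MPV is the signed
version oriented (other − reference); |MPV| = MAPE identically. A zero
pair mean makes both undefined (raised, flagged upstream).

Confound effects are compared with two-sided Wilcoxon signed-rank tests
on subject-matched values (scipy backend; exact null distribution for
small n, normal approximation with tie handling above; verified against
full 2ⁿ sign enumeration for n ≤ 10). Zero differences are dropped —
Wilcoxon's original treatment. The significance threshold is
α / (number of comparisons actually performed × number of methods),
computed at runtime rather than hard-coded, with an `n_tests` override.
Comparisons with fewer than 3 common subjects are skipped and logged.

QC: a bundle fails when its streamline count is below 200 (tractography
failure) or more than 3 sample SDs below its pathway mean; a subject is
removed from a method when more than 20 % of its bundles fail. The SD
rule is evaluated before the absolute floor, each removal records
exactly one reason, and a manual exclusion list (visual QC) can be
supplied.

## Diffusion tensor and variance decomposition

The tensor is fit per voxel in log-signal space with design rows
(1, −b gx², −b gy², −b gz², −2b gx gy, −2b gx gz, −2b gy gz), then
refined by **2** reweighted passes with weights equal to the squared
predicted signal — the standard IRWLLS correction for the log
transform's heteroscedasticity (iteration count exposed; 0 iterations
reproduces plain log-linear least squares). b ≤ 50 s/mm² counts as b0.
Non-positive signals are excluded per voxel rather than clamped; voxels
with fewer than 7 usable volumes are excluded and counted. Eigenvalues
are clamped at 0 before FA = √(3/2 · Σ(λᵢ−λ̄)²/Σλᵢ²) and MD = λ̄.

In-bundle means are plain averages over the ROI. Each contrast is
evaluated twice: with the subject's reference-dataset ROI on both maps
(isolating the acquisition effect at constant ROI) and with each
dataset's own ROI (adding tractography variability); the difference of
the two MAPEs is the tractography-added variance.

## Synthetic study generator

Bundles are tubes around parametric centerlines (straight, circular
arc, helix): each streamline adds a radial offset that is constant
along its length (Gaussian, SD `tube_sd`, default 1 mm) plus a
low-frequency cosine wobble (~30 % amplitude), giving coherent tubes
rather than white-noise scribbles. A branched variant diverts a labeled
fraction of streamlines to a side lobe, providing ground truth for
trunk/branch detection. Defaults: 300 streamlines per bundle (safely
above the 200-streamline QC floor, as for successful tractography),
arc radius 30 mm or straight length 60 mm, 1 mm point spacing.

Confounds map to perturbations: rigid per-streamline Gaussian jitter
(scan and scanner effects), streamline dropout (direction-count
effects), global affines and radius scaling about the centerline
(vendor-style systematic bias), and native-grid coarsening applied at
the voxelization stage, where resolution effects enter a real pipeline.
The packaged severity ordering encodes the qualitative finding the
analysis is designed to surface — rescan mildest (0.5 mm jitter),
cross-scanner intermediate (1.25 mm jitter + 5 % radius scale),
resolution change most disruptive (2.0 mm jitter + 2.4 mm native grid,
since a resolution change alters the reconstructed streamlines
themselves, not just the grid). These magnitudes are generator
definitions, fixed once.

DWI signals follow the single-tensor model Sᵢ = S₀·exp(−bᵢ gᵢᵀ D gᵢ)
with Rician noise of level S₀/SNR (default SNR 30, 1 b0 + 32
quasi-uniform directions at b = 1000 s/mm²). The default tensor field
ramps its eigenvalues along one axis from (1.4, 0.9, 0.9) to
(1.7, 0.3, 0.3) µm²/ms, so both FA and MD carry spatial gradients and
ROI displacement genuinely changes in-bundle means.

Every level (study, subject, bundle, perturbation, noise) draws its
seed from one master seed via a seed sequence; studies are
byte-reproducible, and analysis re-runs produce hash-identical tables.

## What the synthetic bed does not show

The generator has no fiber crossings, no partial-volume or
susceptibility artifacts, no registration error, and does not emulate
the algorithmic differences between bundle-segmentation workflows;
perturbation magnitudes are stipulated rather than estimated from
scanners. Passing tests therefore demonstrate the *correctness of the
measurement machinery* (masks, Dice, shape formulas, statistics, tensor
estimation) and the pipeline's sensitivity ordering under controlled
confounds — not the empirical effect sizes of any real multi-scanner
cohort. Along-tract profiling, surface-distance metrics (Hausdorff),
harmonization and mixed-effects/ICC modeling are out of scope.

## Problem sizes used by the test suite

Unit and property tests run on grids ≤ 64³, bundles of ≤ 500
streamlines and 200-voxel tensor fits; the end-to-end fixtures use 2–3
subjects × 4 datasets × 2 pathways with 300 streamlines per bundle and
2.5 mm DWI grids. These sizes make every oracle comparison exhaustive
while keeping the whole suite in a few minutes on one CPU.
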