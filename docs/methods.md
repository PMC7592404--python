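# Methods

## Signals and pipeline

The pipeline maps one CT volume per patient to a feature vector in five
fixed stages: (1) optional average-intensity projection of a 4-D phase
series; (2) apical cylindrical VOI mask; (3) 16-level uniform
quantisation under a scheme fixed from a reference subject; (4)
voxel-wise 26-neighbour co-occurrence entropy; (5) reduction to summary
features. Cohort statistics (Mann–Whitney, Spearman) sit on top.
Everything downstream of the volume reader is deterministic; the only
randomness in the package lives in the phantom generator.

### Volume conventions

Arrays are indexed `(slice, row, column)` with the slice index
increasing inferior → superior; spacing is `(dx, dy, dz)` mm. DICOM
rescale slope/intercept and NIfTI scl scaling are applied on read, and
nothing else: grey levels stay in whatever offset/scale the source
used. Absolute density values are therefore convention-dependent —
only comparisons under a shared quantisation scheme are meaningful,
which is why the scheme is fixed cohort-wide.

### VOI geometry

The VOI is a right circular cylinder: a 4 cm-diameter circle on 10
consecutive slices (2.5 cm at the expected 2.5 mm thickness). A voxel
belongs iff its in-plane centre is strictly inside the circle — a
reproducible, resolution-independent boundary rule; at 1 mm resolution
the discretised count is within 2 % of πr²h and invariant (to < 2 %)
under in-plane translation. If the input slice thickness differs from
2.5 mm the 10-consecutive-slices semantics wins and a warning is
raised. Placement (`center_xy`, `top_slice`) is configuration: apex
localisation is manual on real scans and supplied by the generator for
phantoms. Automatic placement is out of scope.

### Quantisation

Edges are `n+1` equally spaced values spanning the min–max of the
reference VOI (16 levels by default). Bins are half-open,
`edges[k−1] ≤ v < edges[k]`, with the top edge included in the top
level. Values outside the reference range clip to the end levels and a
warning reports the out-of-range fraction — deliberately: bullae fall
far below a healthy non-smoker's VOI minimum, so in emphysematous
patients a large share of voxels legitimately collapses into level 1.
That collapse is the mechanism by which fixed-reference quantisation
turns "abnormally dark and uniform" into "low entropy". Level spans of
the reference VOI's own min–max (rather than a fixed scanner range) is
an assumption; the scheme records its provenance and serialises to
JSON so a cohort's scheme is auditable.

### Entropy map

Each in-mask voxel gets its own co-occurrence distribution over the 26
surrounding voxels (13 direction vectors and their negatives,
displacement 1 voxel in index space — no physical-distance weighting,
no resampling of anisotropic grids). Neighbours outside the grid or
the mask are skipped, so wall voxels use fewer pairs; a voxel with no
valid neighbour is excluded from the map. Level pairs are accumulated
**order-free**: the pair {a, b} goes once into the upper-triangular
cell (min, max). The matrix therefore describes unordered pairs, at
most 26 cells are occupied, and the per-voxel entropy
H = −Σ p log₂ p is bounded by log₂ 26 ≈ 4.700 bits. (The alternative —
incrementing (a, b) and (b, a) separately — spreads the same 26 pairs
over up to 52 cells and inflates every off-diagonal voxel's score by
up to 1 bit; the order-free form was chosen so the stated bound is
exact. The convention is pinned by oracle tests.) Base-2 logarithms
throughout; healthy-parenchyma phantoms score ≈ 2.1–2.5 bits.

Implementation: all per-voxel matrices are accumulated in a single
`bincount` over `(voxel, cell)` indices and entropies evaluated via a
c·log₂c lookup table on integer counts; a full-sized VOI (~12 500
voxels) maps in ≈ 0.1 s. Cancellation residue (~1e−16) of degenerate
single-cell matrices is snapped to exact zero — the smallest genuine
nonzero entropy of ≤ 26 integer counts is ≈ 0.33 bits, so the 1e−9
snap threshold cannot touch a real value.

### Features

Density statistics use raw grey levels; entropy statistics use the map
(scored voxels only). Median uses the midpoint convention. The mode of
a continuous signal is the midpoint of its most populated bin — the
quantisation bins for density, sixteen equal bins on [0, log₂ 26] for
entropy — ties to the lowest bin. Skewness and excess kurtosis are the
biased population-moment forms m₃/m₂^1.5 and m₄/m₂² − 3; a constant
signal (e.g. the all-zero entropy map of a uniform phantom) reports
0 for both rather than failing. The "low-density low-entropy
subregion" counts voxels with density < threshold AND entropy <
threshold, defaulting to the level-4/5 quantisation edge and 1.0 bit;
both thresholds are configuration.

### Cohort statistics

Fit ⇔ FEV1 ≥ 50 % AND TLCO ≥ 50 % predicted (threshold configurable).
Mann–Whitney is two-sided: exact null distribution for pooled n ≤ 12
without ties, otherwise normal approximation with midrank tie
correction and continuity correction (the variant is fixed and tested
against an independently coded formula). Correlations are Spearman —
consistent with choosing a rank test for skewed data. Raw p-values are
the primary output (single pre-specified texture feature); a
Holm-adjusted column is emitted alongside, clearly labelled, without
changing the headline numbers.

## Phantom generator

The generator emulates exactly what the analysis is sensitive to, and
no more. Healthy parenchyma is a Gaussian-smoothed white-noise field
(mean 250, SD 40 grey levels, 1.5 mm correlation length) threaded by
Poisson-placed bright Gaussian-profile tubes (0.25 cm⁻³, +120 grey
levels, 0.7–1.4 mm radius) standing in for vessels. Emphysema is
modelled as spheres (radius 2–6 mm) that overwrite tissue with a
near-air level (60 ± 6) until the bulla volume fraction reaches the
severity s; 5 grey levels of additive acquisition noise finish the
volume. The default grid (12 × 44 × 44 voxels at 1 × 1 × 2.5 mm)
represents the apical VOI itself plus margin — apex anatomy, chest
wall, CT physics (beam hardening, kernels) and breathing are *not*
modelled, so passing tests demonstrate the pipeline's mechanics and
directional sensitivity, not clinical performance on real scans.

Lung function: fev1 = clamp(88 − 80·s + ε, 10, 130) and
tlco = clamp(76 − 85·s + ε, 10, 130), ε ~ N(0, 6²) independent. With
fit severities ~ U(0, 0.12) and unfit ~ U(0.35, 0.60), simulated group
means land near the fit profile (≈ 85/73 % predicted) and somewhat
below the unfit profile (≈ 50/36 %): one latent severity drives both
measurements *and* the image, and keeping ≥ 90 % of unfit subjects
genuinely below the 50 % threshold forces their severities — hence
their lung function — further from the boundary than a real mixed-cause
cohort, where FEV1 and TLCO fail for partly independent reasons, would
sit. Cohorts default to 29 fit + 32 unfit; patient 1 is forced to
severity 0 and flagged as the quantisation reference (the healthy
non-smoker analogue). One shared RNG per call; per-patient phantom
seeds are drawn from it, so a cohort is reproducible from a single
seed.

## Problem sizes

Unit and oracle tests run on 5–10-voxel grids. The replicate studies
(100 signal + 100 null simulated cohorts) use a reduced phantom
(8 × 24 × 24 grid, 16 mm circle × 8 slices, ~3 000 VOI voxels) —
chosen as the smallest geometry that still gives each patient a
textured, multi-bulla VOI; the effect sizes involved are large enough
that power is unaffected. The analysis scripts and the acceptance
script use the full-sized default phantoms.

## Known limitations

* Absolute density/entropy values depend on the source's grey-level
  convention and on the quantisation reference; only within-scheme
  contrasts are interpretable.
* The severity → lung-function mapping is a single-axis caricature;
  real FEV1/TLCO discordance (e.g. vascular disease lowering TLCO
  alone) is not represented.
* Isolated VOI voxels are dropped from the entropy map rather than
  scored; with a contiguous cylinder this never occurs in practice.
* The per-voxel matrix convention (order-free pairs) is one of several
  defensible GLCM constructions; scores are comparable only within a
  convention.
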