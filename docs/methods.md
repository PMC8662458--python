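# Methods

This note documents the models, parameters and design choices behind
`collateralis`, in the order the pipeline runs them.

## Intensity model and Hounsfield conversion

CBCT scanners deliver gray values that are linearly related to, but not
calibrated as, CT numbers; scatter depresses them relative to true
attenuation. The pipeline therefore applies a per-slice linear brightness
regression `Y = m + wQ` before the rescale affine `HU = Y·RS + RI`. The
defaults `w = 1.0236`, `m = 200` come from a regression fitted on clinical
CBCT data and are configuration, not refit here — no training procedure
for them is defined, and they are best treated as scanner-specific. The
order matters: applying the rescale first and the regression second
differs by `m·RS` and loses vessel contrast; a regression test pins the
order.

`RS`/`RI` are read from the standard DICOM rescale tags (0028,1053) and
(0028,1052). If a series lacks them, the stored values are taken to be in
the default Hounsfield unit (`RS = 1`, `RI = 0`) and the volume records
that with a flag.

## Sliding MIP

Window length defaults to 20 slices with stride 1 in the library
(`sliding_mip`); the orchestrated pipeline uses stride 2 so that the ~22
projections of a 64-slice phantom stay distinct but numerous enough to
sample 125 labeled patches. A 20-slice window at 0.762841 mm spacing is
15.3 mm of tissue; the often-quoted "16 mm slab" is the same setting up to
rounding. Slice indices are 0-based internally and printed 1-based in
provenance strings.

## Skull stripping

The four-step morphological procedure assumes the axial image shows a
bright skull ring separating dark exterior air from mid-intensity brain:
threshold `I < mean(I)`, remove border-connected components (exterior
air), flood-fill holes and keep the largest component (the brain), then
multiply. Component labeling uses 8-connectivity and hole filling
4-connectivity; area ties break toward the smallest top-left bounding-box
coordinate for determinism. The procedure fails loudly (rather than
guessing) when no interior component survives — e.g. on a projection
dominated by a skull cap — and the pipeline skips such projections.

## Denoising and filter selection

Five filters are compared:

* **Anisotropic diffusion** — explicit Perona–Malik scheme, 4-neighbour
  fluxes, exponential conductance `exp(−(∇/κ)²)`; defaults 10 iterations,
  κ = 30, λ = 0.25 (the stability bound). Reflecting boundaries make the
  scheme conserve total intensity, which is tested.
* **Median** — 3×3, reflect padding.
* **Wiener** — locally adaptive: `out = μ + max(0, σ²−ν)/max(σ², ν)·(in−μ)`
  with 3×3 local moments and noise power ν estimated as the mean local
  variance. Implemented directly (the guarded form is well defined on
  flat regions).
* **L1/L2-RTV** — relative-total-variation structure extraction: each
  fixed-point iteration reweights gradients by
  `1/|G_σ∗∇S| · 1/|∇S|` (windowed over pointwise total variation) and
  solves a sparse linear system; the L1 variant uses an IRLS absolute
  data term. Defaults λ = 0.01, σ = 3, 4 iterations — a typical structure
  scale for 256² images; no installed package provides RTV, so it is
  implemented here.

Quality is measured by PSNR (`10·log10(R²/MSE)`, R logged per report since
conventions vary) and SSIM with an 8×8 uniform sliding window,
`c1 = (0.01·L)²`, `c2 = (0.03·L)²`. **Selection is argmax SSIM**, ties to
the first filter in the canonical order; PSNR is reported but never
drives the choice. On phantoms the clean signal is the reference; on real
data the pre-filter image is. Identical images yield an infinite-PSNR
signal, not an error.

## Enhancement

White top-hat with a flat disc of radius 10 px removes every structure
wider than the disc, flattening the background while keeping thin bright
vessels; reflect padding avoids border residuals. A multiscale variant
takes the pixelwise max over a radius set (default `{10}`, i.e. the
single-scale transform). The grayscale erosion is the standard min-of-window
operator (its common printed form as a max is a known typo in the source
literature). Contrast is then stretched linearly between the 1st and 99th
percentiles into [0, 1]; a constant image maps to zero by convention.

## Feature bank (40 = 22 + 11 + 7)

Only the total of 40 and the three groups are externally fixed; the
membership below is this package's documented convention.

* **GLCM (22)** — patches quantized to 8 equal-width levels over their own
  range (256 pixels cannot populate more); co-occurrences counted at the
  four distance-1 offsets, symmetrized, pooled, normalized. Entropies use
  log2 with `0·log 0 := 0`; degenerate marginals give correlation 0. The
  battery merges the Haralick, Soh and Clausi sets, which overlap:
  `inverse_difference` (Clausi) equals the `|i−j|` homogeneity variant;
  both columns are kept for completeness of the canonical 22-name set.
* **Shape (11)** — Otsu-binarize the patch (constant patches count as
  all-foreground), keep the largest 8-connected component, then area,
  perimeter, major/minor axis, eccentricity, solidity plus five factors:
  aspect ratio, circularity `4πA/P²`, compactness `P²/A`, roundness
  `4A/(π·major²)`, extent. Empty foregrounds yield zeros with a warning.
* **Hu moments (7)** — computed on the grayscale patch divided by its
  maximum, making the invariants exact under uniform intensity scaling as
  well as translation; φ7 is invariant under proper rotations and flips
  sign under reflection. An all-zero patch has no defined moments and is
  rejected (the batch table writer substitutes zeros so background
  patches cannot abort a run).

## Classifiers and evaluation

SVM (polynomial kernel, degree 3) and KNN (k = 2, Euclidean) operate on
z-scored features with statistics learned from training folds only; the
decision tree is capped at 100 splits (`max_leaf_nodes = 101`); the
random forest uses 100 trees with `ceil(p/2)` features per split. KNN's
1–1 vote ties resolve toward the nearer neighbour, realized exactly by
distance weighting at k = 2. Continuous scores for ROC are the SVM
decision value or the positive-class proportion.

Cross-validation is stratified 10-fold on 100 patches, with metrics
pooled over out-of-fold predictions (per-fold accuracies also reported);
a 25-patch holdout is evaluated after refitting on all 100. Rows are
canonically ordered before folding so the result is invariant to row
order. FPR is `FP/(FP+TN) = 1 − specificity`; undefined ratios are
reported as NaN, never 0. AUC is the trapezoidal area of the tie-grouped
threshold sweep, which equals the normalized Mann–Whitney pair count.

## Synthetic phantom: what it emulates, and what it does not

The generator renders, on a raw CBCT intensity scale (rescale tags
slope 1 / intercept −250, placing brain background near soft-tissue
display values after brightness adjustment):

* an ellipsoidal skull shell (intensity 900) whose z radius exceeds the
  axial field of view — a mid-head acquisition where every slice shows a
  ring (the mean-threshold stripping procedure requires a ring, not a
  cap);
* brain interior (intensity 60) with a smooth in-plane Gaussian bias
  field (amplitude 10);
* 5 normal vessels: low-curvature cubic splines crossing the brain
  roughly in-plane, radius 1.0 mm, intensity 600;
* 8 collaterals: bounded random walks (step 1.5 mm, direction noise
  std 0.35 rad), radius uniform in [0.2, 0.3] mm — i.e. 0.4–0.6 mm
  diameters, *below* the 0.762841 mm voxel spacing — at an intensity
  factor < 1 of the normal vessels. Sub-voxel tubes are rendered by
  partial-volume weighting (3³ supersampling of boundary voxels), since
  hard masks would make them vanish;
* ring artifacts (constant perturbation on 1-px annuli) and then noise
  (Gaussian by default). Geometry and corruption use independent seeded
  streams, so the clean signal of a seed is unchanged by noise settings.

Ground truth labels every voxel whose center lies in a tube or the shell
(collateral > normal > skull priority on projection) and stores each
centerline in mm. The labeled-patch sampler centers patches on projected
vessel pixels, keeps centers a block apart within a class, and prefers
*pure* centers whose block contains no opposite-class pixel — emulating
expert-marked regions of interest that contain either a collateral or a
normal vessel — falling back to mixed centers only when pure ones run
out.

The "easy" study condition (`easy_spec`) uses noise level 1, ring
amplitude 5 and collateral intensity factor 0.5: a low-noise,
high-contrast setting under which the classes are separable by
construction. The phantom does **not** model cone-beam physics (no
forward projection or reconstruction; artifacts are image-domain), beam
hardening, motion, contrast-agent dynamics, or realistic vascular
topology (no branching trees). Passing the synthetic study therefore
shows the pipeline's machinery is correct and self-consistent — not that
clinical accuracy would match.

## Problem sizes and numerics

Default phantom grid 64×128×128 at 0.762841 mm isotropic spacing — large
enough for ~22 sliding windows and 125 well-separated patches while a
full run completes in well under a minute. Morphology is integer-exact;
trapezoidal AUC is clamped to [0, 1] against floating round-off; the
degenerate contrast stretch maps to zero; DICOM export rounds to int16
(raw scanner values are integral in practice). All randomness flows from
a single seed through named spawned streams (phantom geometry, phantom
corruption, patch sampling, model seeds), so a rerun with the same config
and seed reproduces the feature tables bit-exactly.
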