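# collateralis

Detection of cerebral **collateral vessels** from cone-beam CT (CBCT) head
volumes.

Collateral vessels reroute blood around an occluded artery during ischemic
stroke; their extent strongly predicts treatment outcome, so
neuroradiologists want an objective way to tell them apart from normal
vessels. On CBCT angiography collaterals are hard to see: they are thin
(0.4–0.6 mm diameter, below the typical 0.762841 mm slice spacing), dim,
and tortuous, while the images carry noise, ring artifacts and a
non-uniform illumination bias.

This package implements a classical image-processing pipeline for that
problem, end to end:

1. **Hounsfield conversion** — raw CBCT values `Q` are not calibrated CT
   numbers; each slice is brightness-adjusted with a linear regression
   `Y = m + wQ` (defaults `w = 1.0236`, `m = 200`) and then mapped to
   Hounsfield units with the DICOM rescale affine `HU = Y·RS + RI`.
2. **Sliding maximum intensity projection (MIP)** — image *k* is the
   per-pixel maximum over slices `[k·s, k·s + W − 1]` (default `W = 20`),
   making long vessel segments visible in 2D.
3. **Skull stripping** — threshold below the image mean, clear
   border-connected components, flood-fill holes, keep the largest
   component, multiply the MIP by the resulting brain mask.
4. **Denoising with quality selection** — five candidate filters
   (Perona–Malik anisotropic diffusion, median, adaptive Wiener, L1-RTV
   and L2-RTV structure extraction) are scored with PSNR and SSIM; the
   filter with the highest SSIM is applied.
5. **Vessel enhancement** — white top-hat `f − (f ∘ B)` with a flat disc
   `B` of radius 10 px (optionally the pixelwise max over several radii),
   followed by a percentile contrast stretch.
6. **Feature extraction** — overlapping 16×16 patches (shift 1) are
   described by 40 features: 22 GLCM texture statistics
   (Haralick/Soh/Clausi battery), 11 region-shape descriptors, and the 7
   Hu moment invariants.
7. **Classification** — a degree-3 polynomial SVM, a decision tree
   (≤100 splits), a random forest (half the features per split) and a
   k = 2 nearest-neighbour model are evaluated with stratified 10-fold
   cross-validation on 100 patches plus a 25-patch holdout, reporting
   sensitivity, specificity, accuracy, precision, recall, F-measure and
   ROC-AUC.

Because clinical CBCT stroke data is not public, the package ships a
**synthetic head-phantom generator** with voxel-level ground truth (skull
shell, bias field, thick bright normal vessels, thin dim tortuous
collaterals rendered by partial-volume weighting, Gaussian/speckle/Poisson
noise, ring artifacts). Every stage is tested against it.

## Worked example

```python
from collateralis import RunConfig, run_pipeline

manifest = run_pipeline(RunConfig(seed=1), "run_out")
```

then inspect `run_out/stage4_denoise/quality_report.json`:

```
selected: L2-RTV
Anisotropic diffusion filter  PSNR 38.83  SSIM 0.9618
Median filter                 PSNR 31.63  SSIM 0.9378
Wiener filter                 PSNR 36.29  SSIM 0.9476
L1-RTV                        PSNR 52.72  SSIM 0.9982
L2-RTV                        PSNR 52.78  SSIM 0.9982
```

On this low-noise phantom the RTV filters score the best SSIM against the
clean signal and L2-RTV is selected (on the noisier clinical-like data the
Wiener filter tends to win on SSIM despite a poor PSNR — the selection is
always by SSIM, which tracks preserved vessel structure rather than mean
squared error). `run_out/stage7_classify/summary.json` then reports, for
the 100-patch training table and 25-patch holdout:

```
glcm_svm_poly3       cv_accuracy 100.0  holdout_accuracy 100.0  cv_auc 1.0
glcm_decision_tree   cv_accuracy  98.0  holdout_accuracy 100.0  cv_auc 0.98
glcm_random_forest   cv_accuracy 100.0  holdout_accuracy 100.0  cv_auc 1.0
glcm_knn             cv_accuracy 100.0  holdout_accuracy 100.0  cv_auc 1.0
```

i.e. on a well-separated synthetic condition all four classifiers recover
the collateral/normal distinction from GLCM texture alone, while
label-permuted controls stay at chance (~47 %). Accuracies in the 97–100 %
range are typical across seeds.

A command-line interface wraps the same library:

```sh
collateralis generate --seed 1 --out phantom_out     # DICOM series + truth
collateralis run --config docs/run_example.yaml --out run_out
```

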