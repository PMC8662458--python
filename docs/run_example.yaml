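# Example configuration for `collateralis run --config docs/run_example.yaml`.
# Every key is optional; omitted keys take the defaults shown here.

seed: 1                 # master seed; all stage randomness derives from it

# Input: either a DICOM directory ...
# dicom_dir: /data/cbct_series
# ... or the synthetic phantom (used when dicom_dir is absent):
phantom:
  shape: [64, 128, 128]           # slices, rows, cols (>= 32 each)
  voxel_mm: [0.762841, 0.762841, 0.762841]
  skull_intensity: 900.0
  brain_intensity: 60.0
  bias_amplitude: 10.0            # smooth illumination bias (raw units)
  n_normal: 5                     # thick bright vessels, radius >= 0.8 mm
  normal_radius_mm: 1.0
  normal_intensity: 600.0
  n_collateral: 8                 # thin dim tortuous vessels
  collateral_radius_range_mm: [0.2, 0.3]   # 0.4-0.6 mm diameters
  collateral_intensity_factor: 0.5         # relative to normal vessels
  tortuosity_std_rad: 0.35
  noise_type: gaussian            # gaussian | speckle | poisson
  noise_level: 1.0
  ring_count: 2
  ring_amplitude: 5.0

brightness:             # Y = m + w*Q before Hounsfield conversion
  w: 1.0236
  m: 200.0

mip_window: 20          # slices per sliding MIP window
mip_stride: 2

filter_name: auto       # auto = run all five, pick the best SSIM
tophat_radii: [10]      # disc radii; >1 entry = multiscale top-hat
stretch: [1.0, 99.0]    # contrast-stretch percentiles

block: 16               # patch size
shift: 1
glcm_levels: 8

n_train_per_class: 50   # 100 patches for 10-fold CV
n_test: 25              # holdout size
cv_folds: 10

models: [svm_poly3, decision_tree, random_forest, knn]
feature_groups: [glcm, shape, moment]

write_dicom: false      # also persist the phantom as a DICOM series
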