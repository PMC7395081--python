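# Example pipeline configuration (octmark run --config example_config.yaml)
# Any omitted key keeps its documented default.

seed: 1
folds: 5                      # CV folds for elastic-net hyper-parameter search
l1_grid: [0.001, 0.01, 0.1, 0.3, 0.5, 0.7, 0.9, 1.0]   # mixing-ratio grid

cohort:
  n_patients: 200             # full study scale is 1094
  split: [180, 20]            # train/test, same 9:1 ratio as 985/109
  seed: 1
  geometry:
    dims: [64, 32, 256]       # full acquisition grid is [512, 128, 1024]
    lateral_extent_mm: [6.0, 6.0]
    depth_extent_mm: 2.0
  speckle_sd: 0.12            # multiplicative speckle, pre-normalisation
  intensity_gain: 1.0
  rt_base_um: 300.0           # baseline retinal thickness
  rt_burden_um_per_nl: 0.30   # IRC+SRF thicken the retina
  bcva_model:
    intercept: 62.0           # letter score at zero burden
    target_r2: 0.6            # generative R^2(BCVA | burden)
  llva_model:
    intercept: 45.0
    weight_scale: 1.3         # LLVA is the more morphology-sensitive score
    target_r2: 0.7

local:                        # stage one: per-A-scan auto-encoder
  code_dim: 20
  hidden: [256, 64]
  epochs: 30
  columns_per_volume: 128
  batch_size: 256
  lr: 0.001

global:                       # stage two: volume-level auto-encoder
  code_dim: 20
  pool_shape: [16, 8]
  hidden: [256, 64]
  epochs: 60
  batch_size: 32
  lr: 0.001

zones:                        # conventional-marker quantification zones
  fovea_center_mm: [3.0, 3.0]
  inner_radius_mm: 0.5        # 1 mm central disc
  outer_radius_mm: 1.5        # 3 mm ring boundary
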