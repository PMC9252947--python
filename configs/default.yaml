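phantom:
  shape:
  - 64
  - 64
  - 24
  spacing:
  - 3.0
  - 3.0
  - 3.0
  regions:
  - label: 0
    name: air
    anatomy_value: -1000.0
    uptake_mean: 0.1
    between_scan_sd: 0.01
    within_scan_sd: 0.02
  - label: 1
    name: soft_tissue
    anatomy_value: 40.0
    uptake_mean: 0.8
    between_scan_sd: 0.1
    within_scan_sd: 0.15
  - label: 2
    name: lung
    anatomy_value: -700.0
    uptake_mean: 0.4
    between_scan_sd: 0.05
    within_scan_sd: 0.08
  - label: 3
    name: heart
    anatomy_value: 70.0
    uptake_mean: 2.5
    between_scan_sd: 0.8
    within_scan_sd: 0.4
  lesions:
  - region_label: 2
    radius_mm: 4.0
    amplitude_sd: 5.0
    count: 1
  - region_label: 3
    radius_mm: 4.0
    amplitude_sd: 5.0
    count: 1
  n_train: 60
  n_eval_normal: 6
  n_eval_abnormal: 12
  anatomy_noise_sd: 15.0
  jitter: 0.05
model:
  depth: 3
  base_channels: 4
  dropout_rate: 0.0
  logvar_clamp:
  - -10.0
  - 6.0
  input_norm:
  - -400.0
  - 500.0
  variance_floor: 1.0e-06
  predict_variance: true
train:
  epochs: 20
  batch_size: 16
  learning_rate: 0.001
  seed: 0
  optimizer: adam
  val_fraction: 0.1
  mse_warmup_epochs: 5
  lr_schedule: cosine
anomaly:
  z_threshold: 3.0
  radius_mm: 5.0
  connectivity: 26
  variance_floor: 1.0e-06
  mc_samples: 1
eval:
  suv_thresholds:
  - 1.0
  - 2.0
  abs_error_thresholds:
  - 0.5
  - 1.0
  fp_rates:
  - 1.0
  - 3.0
  - 10.0
out_dir: petnorm_run
resample_mm: 3.0
seed: 0
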