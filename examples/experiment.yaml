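# Desk-scale end-to-end run: lcdbench run --config examples/experiment.yaml
# Scale n_train / epochs / width_scale up for a full-size experiment.
seed: 1
out_dir: lcdbench-run
n_train: 2000
per_cell_present: 20
per_cell_absent: 20
sizes_mm: [5.0, 9.0]
contrast_hu: 10.0
doses: [200.0, 100.0, 50.0, 26.0]
recons: [FBP, ADMIRE]
noise:
  sigma_ref: 10.0
  admire_factor: 0.7
  smooth_px: 0.5
detector:
  width_scale: 0.125
  epochs: 10
  batch_size: 32
n_readers: 12
reader_dprime: 1.0
reader_jitter: 0.3
n_boot: 2000
n_gradcam: 8
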