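# End-to-end demo: a tumour patch and a fibroblast patch in one well,
# oxygen read-out at 20-s intervals for 10 minutes.
seed: 0
analyte: O2
scene:
  grid_shape: [48, 48]
  pixel_size_mm: 0.1
  patches:
    - {shape: rect, params: [8, 8, 20, 20], cell_type: tumour}
    - {shape: rect, params: [28, 28, 40, 40], cell_type: fibroblast}
  cell_types:
    tumour: {density: 66000, k_o2: 1.0e-6, k_ph: 4.0e-9, nucleus_radius_px: 2}
    fibroblast: {density: 20000, k_o2: 2.0e-7, k_ph: 1.0e-9, nucleus_radius_px: 2}
  chamber: {height_mm: 0.1, reference_height_mm: 0.1, D_eff_mm2_per_s: 1.0e-3}
  initial_o2_pct: 100.0
acquisition:
  interval_s: 20.0
  duration_s: 600.0
  read_noise_sd: 5.0
  shot_noise: true
  seed: 0
o2_calibration: {R0: 1.6, Ksv: 0.03, batch_id: synthetic-batch}
smoothing_factor: 2.0
kinetics: {r2_threshold: 0.99, min_fraction: 0.3, min_points: 10}
detection: {k_mad: 5.0, min_area_mm2: 0.1}
nuclei: {min_area_px: 3, max_area_px: 60, declump: watershed, scale: 16}
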