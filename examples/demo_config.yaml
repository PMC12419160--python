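seed: 0
scene:
  image_shape:
  - 96
  - 96
  pixel_size: 160.0
  n_frames: 26
  frame_interval: 15.0
  cell_radius: 34.0
  nucleus_radius: 10.0
  pm_thickness: 3.0
  organelle: pm
  total_probe: 1200000.0
  marker_level: 600.0
  background_offset: 50.0
  nuclear_ratio: 1.0
  poisson_scale: 1.0
  read_sigma: 2.0
  blur_sigma_px: 0.0
optics:
  wavelength: 640.0
  numerical_aperture: 1.45
segmentation:
  preset: pm
  threshold_factor: 0.5
  dilation_cycles: 1
  mode: per-frame
  mask_source: wavelet
quantify:
  denominator: cytosol
  roi_source: ground-truth
  baseline_window: null
  response_window: null
groups:
- name: responder
  n_reps: 3
  cells_per_rep: 2
  kinetics:
    phi0: 0.1
    delta_phi: 0.4
    tau_on: 60.0
    t_stim: 120.0
    t_rev: null
    tau_off: null
- name: attenuated
  n_reps: 3
  cells_per_rep: 2
  kinetics:
    phi0: 0.1
    delta_phi: 0.12
    tau_on: 60.0
    t_stim: 120.0
    t_rev: null
    tau_off: null
stats:
  test: anova
  reference_group: responder
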