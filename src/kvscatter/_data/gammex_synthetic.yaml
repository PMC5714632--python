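# Synthetic bolus/no-bolus consistency experiment on a tissue-insert
# phantom: simulate, contaminate with scatter, correct, reconstruct,
# measure. Sizes are desk-scale; see docs/methods.md for the rationale.
phantom:
  body_radius_mm: 75.0
  grid_shape: [112, 112]
  voxel_size_mm: 2.0
  insert_radius_mm: 9.0
  ring_radius_mm: 47.0
  roi_radius_mm: 6.0
  inserts:  # name, relative electron density (ring-placed, equally spaced)
    - ["LN-lung 300", 0.289]
    - ["Lung 450", 0.403]
    - ["Adipose", 0.924]
    - ["Solid Water", 0.989]
    - ["Brain", 1.049]
    - ["Inner Bone", 1.096]
    - ["CB2 (50%)", 1.470]
    - ["Cortical Bone", 1.695]
bolus:
  thickness_mm: 30.0
  side: top
geometry:
  source_axis_distance: 1000.0
  axis_detector_distance: 500.0
  detector_pixel_pitch: 2.4
  detector_size: 144
  n_angles: 72
spectrum:
  kind: mono
  energy_kev: 60.0
source:
  i0_photons: 1.0e5
  response: energy
  poisson_noise: true
scatter:
  enabled: true
  site_downsample: 4
  n_photons_mc: 150000
  smooth_sigma_px: 5.0
  smooth_sigma_angle: 1.5
scatter_model:
  downsample_factor: 3
  n_sites: 10
  n_exit_samples: 16
correction:
  mode: constant_b
  c: 1.0
  max_iterations: 10
  stop_tolerance: 0.002
reconstruction:
  n_voxels: 64
  n_sweeps: 8
  relaxation: 0.8
  nonnegativity: true
rng_seed: 20260901
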