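grid:
  shape:
  - 96
  - 96
  - 96
  voxel_size_mm:
  - 0.1
  - 0.1
  - 0.1
acquisition:
  field_strength_T: 9.4
  echo_time_s: 0.015
  b0_direction:
  - 0.0
  - 0.0
  - 1.0
inclusions:
- kind: cylinder
  center_mm:
  - -2.4000000000000004
  - -2.4000000000000004
  - 0.0
  axis:
  - 0.0
  - 0.0
  - 1.0
  radius_mm: 0.2
  delta_chi_ppm: 0.06
- kind: cylinder
  center_mm:
  - 0.0
  - 2.4000000000000004
  - 1.2000000000000002
  axis:
  - 1.0
  - 0.0
  - 0.0
  radius_mm: 0.2
  delta_chi_ppm: 0.06
- kind: cylinder
  center_mm:
  - 2.4000000000000004
  - 0.0
  - 0.0
  axis:
  - 0.7071067811865476
  - 0.0
  - 0.7071067811865476
  radius_mm: 0.2
  delta_chi_ppm: 0.06
background_chi_ppm: 0.0
tissue_magnitude: 1.0
canal_magnitude_factor: 0.8
noise_sd: 0.0
rng_seed: 1234
background_field_ppm:
  z: 0.03
  x: 0.01
  xx: 0.002
  zz: -0.002
texture_sd: 0.08
texture_corr_mm: 1.6
phase_sign: -1.0
antialias: true
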