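schema: neckdyn-run-1
seed: 2024
anatomy_file: null
muscle_file: null
anatomy:
  spacing_c0_c2_mm: 22.0
  spacing_c2_c7_mm: 19.0
  lordosis_apex_mm: 4.0
  head_mass_kg: 4.5
  head_com_anterior_mm: 10.0
  head_com_up_mm: 42.0
  head_inertia_kg_m2: 0.018
  vertebra_mass_kg: 0.25
  vertebra_inertia_kg_m2: 0.0005
  joint_arm_mm:
  - 10.5385
  - 10.0132
  - 2.0
  - 1.2
  - -0.6
  - -0.45
  - -0.375
  - -0.375
  joint_stiffness_nm_rad:
  - 1.5
  - 1.5
  - 1.9
  - 2.1
  - 2.4
  - 2.6
  - 2.8
  - 3.0
  joint_scale:
  - 27.8005
  - 198.5086
  - 236.4011
  - 400.0
  - 480.9626
  - 298.7974
  - 298.7974
  - 75.5
  extension_stiffness_ratio: 1.0
  damping_ratio: 0.11
  k_axial_n_m: 600000.0
  k_shear_n_m: 400000.0
  c_trans_n_s_m: 600.0
  bilateral_factor: 2.0
  attachment_jitter_mm: 0.25
  gravity: false
schedule:
  reflex_time_ms: 80.0
  rise_time_ms: 10.0
  plateau: 0.72
  shape: linear
profile:
  ramp_rate_g_s: 125.0
  ramp_end_ms: 80.0
  plateau_g: 10.0
  total_duration_ms: 150.0
  g_value: 9.81
scenarios:
- none
- passive
- active
solver:
  dt_ms: 0.01
  sample_interval_ms: 0.5
gravity: null
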