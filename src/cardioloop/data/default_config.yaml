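geometry:
  ed_cavity_volume: 158.3
  wall_volume: null
  base_to_apex_length: 85.0
  truncation_fraction: 0.4
  wall_thickness: 10.8
  n_transmural: 3
  n_axial: 6
  n_circumferential: 12
  endo_helix_angle: 60.0
  epi_helix_angle: -60.0
  n_pericardial: 49
  k_pericardial_apex: 5.0
  k_pericardial_base: 2.0
  root_weights:
    septal: 0.4
    anterior: 0.3
    posterior: 0.2
    lateral: 0.1
  root_motion_ratio: 0.72
  seed: 0
passive:
  a: 0.00039
  b: 3.7
  a_f: 0.0019
  b_f: 14.0
  a_s: 0.0011
  b_s: 11.0
  a_fs: 3.6e-07
  b_fs: 0.00078
  tissue_label: ventricle
active:
  Tmax: 0.2
  Ca0: 4.35
  Ca0max: 4.35
  B: 4750.0
  l0: 0.00158
  lr: 0.00185
  t0: 0.35
  m: 950.0
  b_relax: -1.5
  tissue_label: ventricle
circulation:
  r_av: 0.02
  r_mv: 0.03
  r_sys: 0.92
  r_ven: 0.04
  c_art: 1.7
  c_ven: 9.0
  total_blood_volume: 3346.0
  v_art_slack: 420.0
  v_ven_slack: 2450.0
  v_la_slack: 20.0
  la_passive_elastance: 0.25
  la_active_elastance: 0.35
  la_active:
    Tmax: 0.1
    Ca0: 4.35
    Ca0max: 4.35
    B: 4750.0
    l0: 0.00158
    lr: 0.00185
    t0: 0.05
    m: 1048.9
    b_relax: -1.5
    tissue_label: atrium
  la_activation_time: 0.82
  cycle_period: 1.0
edp_reference: 11.85
fiber_prestretch: 1.12
blend_width: 0.5
solver_tol: 1.0e-08
root_rest_position: 0.0
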