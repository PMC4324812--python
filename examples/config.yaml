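grid:
  n_x: 100
  n_y: 100
  n_z: 100
  spacing: 10.0
network:
  line_spacing: 10
  mvd_multiplier: 1.0
  capillary_link_prob: 0.3
  wall_thickness: 1.0
flow:
  sigma_T: 0.82
  pi_v: 20.0
  pi_i: 15.0
  K: 4.13
  S_over_V: 0.02
  delta_P_drive: 3.5
  P_outlet: 15.0
  mu_plasma: 9.000765065030527e-06
  H_inlet: 0.45
  Lp_normal: 0.00035999999999999997
  tol_couple: 1.0e-06
  max_picard_iter: 60
  tol_interstitial: 1.0e-10
  relax: 1.0
chem:
  D_m: 0.1
  delta_ecm: 130000000000.0
  mu_T: 1.7e-12
  mu_E: 3.0e-13
  lambda_mde: 1.7e-08
  D_o: 1000.0000000000001
  gamma: 6.25e-11
  alpha: 1.27e-15
  C_Hb: 2.03e-11
  P50: 26.0
  hill_n: 2.7
  P_O2_inlet: 100.0
  wall_o2_transfer_ref: 5.0
  inner_dt: 5.0
  tol_chem: 1.0e-06
  max_inner_iter: 5000
  sweep_every: 2
  point_source_rate: 1.0e-12
cells:
  theta_prol: 0.3
  theta_surv: 0.05
  T_TC: 6
  necrotic_lifetime: 30
  p_clear: 0.2
  n_seed_cells: 20
  seed_region: 5
vessel:
  dilation_rate: 0.4
  R_max: 20.0
  Lp_tumour: 0.0028000000000000004
  E: 6.5
  b: 0.1
  P_c: 2.0
  tau_crit_frac: 0.5
  p_collapse_unit: 0.05
n_steps: 200
step_hours: 1.5
oxygen_mode: flow_dependent
seed_network: 1
seed_cells: 2
seed_collapse: 3
snapshot_every: 0
enable_cooption: true
enable_remodelling: true
enable_collapse: true
output_dir: null
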