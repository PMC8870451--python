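# Demo configuration: all stages, small sizes, explicit seed.
seed: 12345
output_dir: ionbind_out
stages: [simulate, shells, rotamers, hbonds, amd, pb, phylo]

analysis:
  first_shell_protein: 2.8
  first_shell_water: 3.0
  second_shell: 6.0
  bridge_water: 3.0
  hbond_dist: 3.5
  hbond_angle_dev: 30.0
  rotamer_filter_window: 50.0

site:
  n_replicas: 3
  n_frames: 100
  frame_interval: 1.0
  noise_sd: 0.02
  water_count: 4
  first_fraction: 0.6
  second_fraction: 0.2

amd:
  n_frames: 1500
  dt: 0.1
  dihedral_mean: 500.0
  dihedral_sd: 10.0
  potential_mean: -50000.0
  potential_sd: 100.0
  window: [20.0, 120.0]
  lambda_factor: 0.3
  n_atoms: 10000

pb:
  eps_in: 8.0
  eps_out: 80.0
  sigma: 0.7
  ionic_strength: 0.15
  scale: 1.8
  fill_ratio: 0.7
  grid_points: 41
  dielectric_model: gaussian

phylo:
  n_leaves: 8
  sequence_length: 120
  branch_length: 0.15
  identity_threshold: 0.90
  n_bootstrap: 50
  distance_correction: none
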