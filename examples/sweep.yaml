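# Cutoff-radius sweep config for `liquidprops sweep`
system:
  catalog: polar_liquid
  n: 80
ensemble:
  ensemble: NVT
  T_target: 300.0
  thermostat: nose_hoover
  dt: 0.5
  r_on: 4.0
  r_off: 6.0
  seed: 0
protocol:
  equilibration_len: 4.0
  production_len: 15.0
  n_restarts: 2
  restart_discard: 1.0
  nvt_len: 15.0
  log_stride: 100
  traj_stride: 100
  density: 0.95
  rdf_species: [O, O]
  cutoff_ladder: [3.5, 6.0]
  seed: 29
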