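# Full workflow config for `liquidprops protocol`
system:
  catalog: polar_liquid
  n: 64
ensemble:
  ensemble: NPT
  T_target: 300.0
  P_target: 1.0
  thermostat: langevin
  friction: 1.0
  dt: 0.5
  r_on: 4.5
  r_off: 6.0
  seed: 0
protocol:
  equilibration_len: 5.0    # ps
  production_len: 50.0
  n_restarts: 5
  restart_discard: 5.0
  nvt_len: 175.0
  gas_len: 50.0
  log_stride: 100
  traj_stride: 100
  density: 0.95             # g/cm3
  rdf_species: [O, O]
  seed: 1
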