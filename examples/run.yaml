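# One-off simulation config for `liquidprops simulate`
system:
  catalog: lj_fluid
  n: 108
ensemble:
  ensemble: NVT
  T_target: 300.0
  thermostat: langevin
  friction: 1.0
  dt: 0.5
  r_on: 7.0
  r_off: 8.0
  seed: 1
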