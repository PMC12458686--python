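# liquidprops

Condensed-phase property analysis for molecular simulations of homogeneous
liquids, packaged with a self-contained toy molecular-dynamics engine so that
every estimator can be exercised, validated and benchmarked at desk scale —
no GPU, no external trajectories.

The package is aimed at people who validate interaction models (force fields,
machine-learned potentials) against bulk-liquid observables and want the
*analysis* layer — fluctuation estimators, structure, transport, convergence
monitoring, repeat statistics — as tested, reusable code with known closed-form
behavior on reference systems.

## What it computes

From NPT observable series (volume `V`, enthalpy `H = E + PV`, energies
logged at a fixed stride):

- **Heat of vaporization** ΔH_vap = ⟨E_gas⟩ − ⟨E_liquid⟩/N + RT
- **Isothermal compressibility** κ = ⟨ΔV²⟩ / (k_B T ⟨V⟩)
- **Isobaric heat capacity** C_p = ⟨ΔH²⟩ / (N R T²)
- **Thermal expansion coefficient** α = Cov(V, H) / (R T² ⟨V⟩)
- **Density** ρ̂ = ⟨m/V⟩, plus the signed relative error
  ε_rel = (x̂ − x_exp)/x_exp against experimental references

From NVT trajectories:

- **Radial distribution functions** g(r) with per-frame minimum-image
  distances, half-open bins and exact shell-volume normalization
- **Mean squared displacement** over all time origins (FFT algorithm,
  held equal to the O(T²) double loop by tests) and the Einstein
  self-diffusion coefficient D = (1/6) d MSD/dt

Around these: cumulative-average convergence series, autocorrelation-corrected
standard errors (statistical inefficiency g = 1 + 2Σc(τ)), inter-repeat
statistics, and a full equilibrate → produce → restart × n → NVT protocol
with a cutoff-radius sweep that reproduces the classic truncation artifact:
too-short interaction cutoffs over-structure a polar liquid and slow its
diffusion.

The toy engine integrates flexible molecules (switched Lennard-Jones +
damped shifted-force Coulomb + harmonic bonds) with velocity Verlet, BAOAB
Langevin or Nosé–Hoover thermostats, and a Metropolis Monte Carlo barostat.
A Gaussian surrogate generates (V, H) series with prescribed κ, C_p, α for
estimator calibration. Everything is deterministic given a seed.

## Worked example

An ideal gas under the Monte Carlo barostat has exact closed forms
(κ = 1/P, α = 1/T, C_p = 5R/2), making it the canonical end-to-end check:

```python
import numpy as np
from liquidprops import (EnsembleSpec, Frame, ideal_gas, run_simulation,
                         isothermal_compressibility, heat_capacity,
                         thermal_expansion, series_stats)
from liquidprops.units import R_KJ_PER_MOL_K, ATM_A3_TO_KJ_PER_MOL

spec = ideal_gas(200)                       # 200 non-interacting particles
V0 = 200 * R_KJ_PER_MOL_K * 300 / ATM_A3_TO_KJ_PER_MOL
frame = Frame(np.random.default_rng(1).uniform(0, V0**(1/3), (200, 3)),
              V0**(1/3))
ens = EnsembleSpec(ensemble="NPT", T_target=300.0, P_target=1.0,
                   thermostat="langevin", barostat_interval=10, seed=2)
res = run_simulation(frame, spec, ens, 600_000, log_stride=5)
V = res.series["V"].slice_time(5000.0)      # discard 5 ps equilibration
H = res.series["H"].slice_time(5000.0)
print(isothermal_compressibility(V, 300.0))
print(heat_capacity(H, 200, 300.0))
print(thermal_expansion(V, H, 300.0))
```

Output:

```
kappa = 0.985006 1/atm
Cp = 20.0576 J/(mol K)
alpha = 0.00324223 1/K
```

i.e. κ within 1.5% of 1/P = 1 atm⁻¹, C_p within 3.5% of
5R/2 = 20.79 J/(mol K), and α within 3% of 1/T = 3.33×10⁻³ K⁻¹ — each
limited only by the finite sample of the volume/enthalpy fluctuations.

## Command line

```bash
liquidprops simulate --config run.yaml --steps 100000     # frames + series
liquidprops thermo --series-dir out -T 300 --n-molecules 64 --total-mass 2556
liquidprops rdf --traj frames.xyz --sel-a O --sel-b O --dr 0.05
liquidprops msd --traj nvt.xyz --topology system.yaml --fit 10:50%
liquidprops protocol --config protocol.yaml --out bundle/  # full workflow
liquidprops sweep --config sweep.yaml                      # cutoff ladder
liquidprops report --bundle bundle/ [--references refs.yaml]
```

Trajectories are extended-XYZ (cubic lattice record per frame); series are
two-column CSV; configuration is YAML mirroring the `SystemSpec`,
`EnsembleSpec` and `ProtocolSpec` dataclasses (see `examples/`).

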