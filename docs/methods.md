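# Methods

This note documents the models, estimator conventions, numerical choices and
known limitations of `liquidprops`. It is the package's own account of its
science; every number quoted here is computed by the test suite or the
acceptance script, not asserted from elsewhere.

## Units and bookkeeping

Internal units are Å (length), fs (time), amu (mass), K (temperature) and
atm (pressure). Energies are kept *per mole of systems* in kJ/mol, which has
two convenient consequences: the mechanical energy unit amu·Å²/fs² is exactly
10⁴ kJ/mol (amu ≡ g/mol), and the per-particle Boltzmann constant k_B·T is
numerically R·T in kJ/mol. The fluctuation formulas are therefore written
once with R and are correct whether one reads the energies per system or per
mole of systems. All estimators convert at the boundary: κ to atm⁻¹ (bar⁻¹
in `meta`), C_p to J/(mol K) per mole of molecules, D from Å²/fs to cm²/s
(factor 0.1).

## Fluctuation estimators

For NPT series logged at a fixed stride:

- ΔH_vap = ⟨E_gas⟩ − ⟨E_liquid⟩/N + RT. **Potential** energies are used for
  both phases: for classical flexible molecules the kinetic and intramolecular
  contributions cancel between gas and liquid, which makes the
  interaction-free limit exactly RT (verified to estimator error by a test
  with a non-interacting diatomic liquid). Total-energy inputs work too —
  the estimator only sees series — but potential energy is the documented
  convention.
- κ = (⟨V²⟩−⟨V⟩²)/(k_B T ⟨V⟩), C_p = ⟨ΔH²⟩/(N R T²),
  α = Cov(V,H)/(R T² ⟨V⟩). All fluctuations are **population** (biased)
  variances/covariances, matching the ⟨X²⟩−⟨X⟩² form; no Bessel correction.
  N is the number of *molecules*, and C_p is reported per mole of molecules —
  the convention under which liquid heat capacities are tabulated.
- α requires time-aligned V and H samples; misaligned series raise an error
  rather than being interpolated.
- Density is ρ̂ = ⟨m/V_i⟩, the mean of instantaneous densities; the
  alternative m/⟨V⟩ is carried in the estimate's metadata (Jensen's
  inequality makes ⟨m/V⟩ ≥ m/⟨V⟩; the difference is second order in the
  relative volume fluctuation and negligible for liquids).

Standard errors of single runs use the statistical inefficiency
g = 1 + 2Σ_τ c(τ) with the sum truncated at the first non-positive
autocorrelation, n_eff = n/g; the naive √(var/n) error is reported alongside,
since multi-run protocols use the inter-repeat standard deviation instead and
single-run error conventions differ between groups.

## Toy engine

The engine exists to generate data whose correct answers are known.

- **Potential**: Lennard-Jones with Lorentz–Berthelot combination between all
  intermolecular pairs and non-bonded intramolecular pairs (directly bonded
  1-2 pairs are excluded); multiplied by the CHARMM switching polynomial
  S(r) = (r_off²−r²)²(r_off²+2r²−3r_on²)/(r_off²−r_on²)³ between r_on and
  r_off. Optional partial charges interact through damped shifted-force
  Coulomb (damping 0.2 Å⁻¹) whose energy and force both vanish at r_off —
  a short-range stand-in chosen so that cutoff-truncation experiments are
  possible without Ewald sums. Harmonic bonds U = ½k(r−r0)². Forces are the
  exact negative gradient (finite-difference tested to 1e-6 relative).
- **Integration**: velocity Verlet; Langevin via the BAOAB splitting
  (friction default 1/ps); Nosé–Hoover as a single chain with coupling mass
  Q = n_dof·k_B T·τ², τ = 100 fs. Default Δt = 0.5 fs, appropriate for the
  stiffest bonds in the catalog (periods ≳ 14 fs).
- **Pressure control**: Metropolis Monte Carlo volume moves every 25 steps
  (configurable), proposals uniform in V, acceptance
  min(1, exp(−[ΔU + PΔV − N_mol k_B T ln(V′/V)]/k_B T)), molecular centers
  scaled so intramolecular geometry is untouched. This samples the NPT
  density p(V) ∝ V^N exp(−β[U+PV]) exactly; for a non-interacting gas
  ⟨N k_B T/V⟩ = P with no finite-N offset, and ⟨V⟩ = (N+1)k_B T/P. The
  maximum step adapts every 50 attempts toward ≈40% acceptance.
- **Degrees of freedom**: Langevin thermostats every degree of freedom, so
  no center-of-mass removal is applied and n_dof = 3N. NVE and Nosé–Hoover
  conserve momentum; there the COM velocity is removed at initialization and
  every 1000 steps and n_dof = 3N−3 (consistently in T_inst and in the
  Nosé–Hoover target). Removing the COM at initialization matters: without
  it the first periodic removal discards the momentum inherited from a
  previous stage and shows up as a spurious NVE energy drop.
- **Neighbor list**: a Verlet list over the static pair table with a 1 Å
  skin, rebuilt when any atom has moved more than skin/2 or the box changed.
  The list is exact — tests require bitwise-equal energies and forces
  against the full pair sum.
- A blown-up state (non-finite energy or coordinates, including coincident
  atoms) aborts with the step index.

Everything is driven by one `numpy` `Generator` per run, so identical
(system, ensemble, seed) give bitwise-identical trajectories and series.

## Synthetic data: what it emulates and what it does not

- The **toy liquids** (monatomic LJ fluid; flexible 3-site polar molecule
  with charges −0.8/+0.4 e and a bond-triangulated bent geometry; generic
  flexible chains at the published system sizes) reproduce the *structure*
  of the workflow — ensembles, thermostats, logging, restarts — and the
  qualitative physics of dense liquids: realistic g(r) shapes, diffusive
  MSD, pressure/temperature control. They do not emulate real water
  (no angle terms, no Ewald electrostatics, no polarizability), so passing
  tests validate estimators and protocol logic, not force-field accuracy.
- The **system builder** places molecules on a cubic lattice with random
  orientations at an exactly honored mass density, retrying orientations
  until every intermolecular pair distance exceeds 0.8·σ_ij.
- The **Gaussian surrogate** inverts the three fluctuation estimators: it
  draws i.i.d. bivariate-normal (V, H) with Var(V) = κ k_B T ⟨V⟩,
  Var(H) = C_p N R T², Cov(V,H) = α R T² ⟨V⟩ (Cauchy–Schwarz checked).
  It has no serial correlation, so it calibrates the estimators' algebra and
  convergence (error ∝ 1/√n), not their behavior on correlated data — the
  engine covers that.

## Protocol and problem sizes

The full workflow is equilibrate (NPT) → initial production → n independent
restart productions with freshly drawn velocities (a re-equilibration span
discarded from each) → inter-repeat mean ± sample standard deviation → one
NVT leg for RDF and MSD/D. Default toy lengths are 5 ps equilibration, 50 ps
production, 5 restarts and 175 ps NVT at Δt = 0.5 fs — a deliberate ~20×
reduction of the nanosecond-scale workflow the protocol mirrors, chosen so
the whole pipeline runs in minutes on one CPU; the stage lengths are plain
configuration fields and scale up unchanged.

Validation runs use: a 108-particle argon-like LJ liquid (σ = 3.4 Å,
ε = 0.996 kJ/mol, m = 39.948 amu, ρ = 1.4 g/cm³) for thermostat set points;
200 non-interacting particles for the barostat and the ideal-gas closed
forms (κ = 1/P, α = 1/T, C_p = 5R/2, all within 5% at ≥10⁵ logged samples);
1000 free Langevin particles for D = k_B T/(mγ) (within 5%); and an
80-molecule polar liquid for the cutoff sweep.

## Cutoff sweep

The sweep runs the identical NVT structure/transport leg per cutoff in a
user-supplied ladder (each cutoff must stay below half the box length,
checked before any simulation starts) with repeat-based error bars, and
tabulates the RDF first-peak height, first-minimum depth and D. On the
polar toy liquid, truncating at 3.5 Å versus 6.0 Å raises the O–O first
peak well beyond the combined repeat errors and lowers D — the classic
over-structuring/slow-down signature of too-short interaction ranges in
polar liquids. The r_on companion of a swept r_off is set to
max(r_off/2, r_off − 2 Å).

## Numerical choices and tie-breaks

- RDF bins are half-open [r, r+dr): a distance exactly on an edge goes to
  the bin whose lower edge it is (implemented as ⌊d/dr⌋ — fixed tie-break,
  bitwise reproducible). Distances exactly at L/2 are excluded (ambiguous
  minimum image). Per-frame normalization uses the instantaneous density
  and the exact shell volume (4/3)π[(r+dr)³−r³]; normalization by the
  trajectory-mean density is available for NVT-vs-NPT comparisons. The fast
  path is a periodic k-d tree; tests pin it to the naive double loop with
  exact histogram-count equality.
- MSD averages over all molecules and all time origins via the FFT
  correlation identity, pinned to the O(T²) loop at 1e-9 relative. The
  lag-0 value is set to exactly zero. Default D fit window is 10–50% of the
  maximum lag — past the ballistic onset, before the poorly averaged long
  lags — and the window plus fit r² are always reported; a low r² flags a
  fit outside the diffusive regime. System COM drift is subtracted by
  default (toggleable, recorded) since thermostat drift biases D; no
  finite-size correction is applied.
- Unwrapping adds the per-step minimum image to make coordinates continuous
  and errors out if a frame-to-frame displacement reaches L/2 (log frames
  more densely). Re-wrapping recovers the input.
- The cumulative convergence series re-evaluates the full estimator on
  growing prefixes at multiples of a window (default 5 ps), so its final
  point equals the full-series estimate exactly.

## Known limitations

- No Ewald/PME electrostatics, no constraints (SHAKE/SETTLE), no rigid
  bodies, no triclinic boxes, no binary trajectory formats. Single cubic
  box, identical molecules per system.
- The engine is FP64 throughout; no reduced-precision mode.
- ΔH_vap carries no finite-size or long-range tail corrections; C_p has no
  quantum/vibrational correction.
- The statistical-inefficiency error bar is itself noisy for short series;
  for production numbers the protocol's inter-repeat standard deviation is
  the more reliable uncertainty, and both are exposed.
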