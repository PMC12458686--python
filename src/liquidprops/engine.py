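"""Toy molecular-dynamics engine: velocity Verlet with Langevin (BAOAB) or
Nosé–Hoover temperature control and a Metropolis Monte Carlo barostat.

The engine exists to exercise the property estimators under controlled,
desk-scale conditions: NVE runs conserve energy, NVT runs hold the kinetic
temperature at the set point, NPT runs hold the mean pressure at the set
point, and a non-interacting system reproduces the ideal-gas closed forms
(⟨V⟩ = N kB T / P, κ = 1/P, α = 1/T, C_p = 5R/2) exactly in the long run.

All simulations are deterministic given (system, ensemble, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .forcefield import ForceField
from .frames import Frame, Trajectory
from .series import ScalarSeries
from .system import SystemSpec
from .units import (ATM_A3_TO_KJ_PER_MOL, MECH_TO_KJ_PER_MOL,
                    R_KJ_PER_MOL_K)

_COM_REMOVAL_STRIDE = 1000
_NH_TAU_FS = 100.0


@dataclass
class EnsembleSpec:
    """Which ensemble to sample and how.

    dt in fs; friction in 1/ps; T_target in K; P_target in atm;
    r_on/r_off is the switching window in Å.
    """

    ensemble: str = "NVT"
    T_target: float = 300.0
    P_target: float = 1.0
    thermostat: str = "langevin"      # langevin | nose_hoover | none
    friction: float = 1.0
    barostat_interval: int = 25
    barostat_max_dlnV: float = 0.02
    dt: float = 0.5
    r_on: float = 10.0
    r_off: float = 12.0
    seed: int = 0
    remove_com: bool | None = None    # default: engine policy per thermostat

    def __post_init__(self) -> None:
        if self.ensemble not in ("NVE", "NVT", "NPT"):
            raise ValueError(f"unknown ensemble {self.ensemble!r}")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if not (0 < self.r_on < self.r_off):
            raise ValueError("need 0 < r_on < r_off")
        if self.ensemble == "NVE":
            self.thermostat = "none"
        if self.ensemble == "NPT" and self.thermostat == "none":
            raise ValueError("NPT requires a thermostat")
        if self.ensemble == "NVT" and self.thermostat == "none":
            raise ValueError("NVT requires a thermostat")


@dataclass
class SimulationResult:
    final_frame: Frame
    series: dict[str, ScalarSeries]
    trajectory: Trajectory | None
    barostat_acceptance: float | None
    seed: int
    n_steps: int


def maxwell_boltzmann_velocities(masses: np.ndarray, T: float,
                                 rng: np.random.Generator) -> np.ndarray:
    """Draw velocities in Å/fs from the Maxwell–Boltzmann distribution."""
    kT_mech = R_KJ_PER_MOL_K * T / MECH_TO_KJ_PER_MOL
    sigma = np.sqrt(kT_mech / masses)[:, None]
    return rng.normal(size=(len(masses), 3)) * sigma


def _remove_com_velocity(vel: np.ndarray, masses: np.ndarray) -> None:
    vcom = np.average(vel, axis=0, weights=masses)
    vel -= vcom


def _kinetic_energy(vel: np.ndarray, masses: np.ndarray) -> float:
    return 0.5 * float(np.sum(masses[:, None] * vel * vel)) * MECH_TO_KJ_PER_MOL


class _MonteCarloBarostat:
    """Metropolis volume moves (uniform in V) with molecule-center scaling.

    Acceptance: min(1, exp(−[ΔU + P ΔV − N_mol kB T ln(V'/V)] / kB T)),
    which samples the NPT volume distribution p(V) ∝ V^N exp(−β[U + PV])
    exactly (so ⟨N kB T / V⟩ = P for an ideal gas).  The maximum step is
    adapted every 50 attempts toward ~40% acceptance, starting from the
    fractional step ``barostat_max_dlnV`` of the initial volume.
    """

    def __init__(self, ens: EnsembleSpec, spec: SystemSpec, V0: float):
        self.P = ens.P_target
        self.T = ens.T_target
        self.n_mol = spec.n_molecules
        self.max_dV = ens.barostat_max_dlnV * V0
        self.attempted = 0
        self.accepted = 0
        self._window_att = 0
        self._window_acc = 0

    def attempt(self, pos, box, ff, has_interactions, mol_index, rng):
        """Returns (pos, box, moved: bool)."""
        self.attempted += 1
        self._window_att += 1
        V = box ** 3
        V_new = V + rng.uniform(-self.max_dV, self.max_dV)
        if V_new <= 0.0:
            return pos, box, False
        box_new = V_new ** (1.0 / 3.0)
        scale = box_new / box
        # scale molecular centers, preserving intramolecular geometry
        com = np.zeros((self.n_mol, 3))
        np.add.at(com, mol_index, pos)
        counts = np.bincount(mol_index, minlength=self.n_mol)[:, None]
        com /= counts
        pos_new = pos + (scale - 1.0) * com[mol_index]
        if has_interactions:
            u_old = ff.evaluate_raw(pos, box).potential
            if ff.r_off >= box_new / 2.0:
                raise RuntimeError(
                    "barostat move would shrink the box below 2·r_off")
            u_new = ff.evaluate_raw(pos_new, box_new).potential
            dU = u_new - u_old
        else:
            dU = 0.0
        kT = R_KJ_PER_MOL_K * self.T
        dW = (dU + self.P * (V_new - V) * ATM_A3_TO_KJ_PER_MOL
              - self.n_mol * kT * np.log(V_new / V))
        if dW <= 0.0 or rng.uniform() < np.exp(-dW / kT):
            self.accepted += 1
            self._window_acc += 1
            pos, box, moved = pos_new, box_new, True
        else:
            moved = False
        if self._window_att >= 50:
            rate = self._window_acc / self._window_att
            if rate > 0.5:
                self.max_dV = min(self.max_dV * 1.1, 0.3 * box ** 3)
            elif rate < 0.3:
                self.max_dV = self.max_dV / 1.1
            self._window_att = 0
            self._window_acc = 0
        return pos, box, moved

    @property
    def acceptance(self) -> float:
        return self.accepted / self.attempted if self.attempted else 0.0


def run_simulation(frame: Frame, spec: SystemSpec, ens: EnsembleSpec,
                   n_steps: int, log_stride: int = 100,
                   traj_stride: int | None = None) -> SimulationResult:
    """Integrate the system and log observables every ``log_stride`` steps.

    Returns logged series V, E_pot, E_kin, T_inst, P_inst and H
    (H = E_pot + E_kin + P_target·V).  Frames are retained every
    ``traj_stride`` steps when given (with velocities), otherwise only the
    final frame is kept.
    """
    rng = np.random.default_rng(ens.seed)
    masses = spec.atom_masses()
    n_atoms = spec.n_atoms
    pos = frame.positions.copy()
    box = float(frame.box_length)
    ff = ForceField(spec, ens.r_on, ens.r_off, periodic=True)
    has_interactions = (np.any(ff._eps != 0.0) or np.any(ff._qq != 0.0)
                       or len(ff._bi) > 0)

    if frame.velocities is not None:
        vel = frame.velocities.copy()
    else:
        vel = maxwell_boltzmann_velocities(masses, ens.T_target, rng)
        _remove_com_velocity(vel, masses)

    remove_com = ens.remove_com
    if remove_com is None:
        # Langevin thermostats every dof; COM removal only for the
        # momentum-conserving integrators
        remove_com = ens.thermostat in ("none", "nose_hoover")
    if remove_com:
        # do it up front so the periodic removal never drains energy
        _remove_com_velocity(vel, masses)
    n_dof = 3 * n_atoms - (3 if remove_com else 0)

    dt = ens.dt
    gamma = ens.friction / 1000.0  # 1/ps → 1/fs
    kT_mech = R_KJ_PER_MOL_K * ens.T_target / MECH_TO_KJ_PER_MOL
    if ens.thermostat == "langevin":
        c1 = np.exp(-gamma * dt)
        c2 = np.sqrt((1.0 - c1 * c1) * kT_mech / masses)[:, None]
    nh_zeta = 0.0
    nh_Q = n_dof * kT_mech * _NH_TAU_FS ** 2

    barostat = None
    mol_index = spec.molecule_of_atom()
    if ens.ensemble == "NPT":
        barostat = _MonteCarloBarostat(ens, spec, box ** 3)

    inv_m = 1.0 / (masses[:, None] * MECH_TO_KJ_PER_MOL)

    def forces_at(p, b):
        if not has_interactions:
            return 0.0, np.zeros_like(p), 0.0
        rep = ff.evaluate_raw(p, b)
        return rep.potential, rep.forces, rep.virial

    e_pot, forces, virial = forces_at(pos, box)

    def nh_half(v):
        nonlocal nh_zeta
        ke2 = 2.0 * _kinetic_energy(v, masses) / MECH_TO_KJ_PER_MOL
        nh_zeta += 0.25 * dt * (ke2 - n_dof * kT_mech) / nh_Q
        v = v * np.exp(-0.5 * dt * nh_zeta)
        ke2 = 2.0 * _kinetic_energy(v, masses) / MECH_TO_KJ_PER_MOL
        nh_zeta += 0.25 * dt * (ke2 - n_dof * kT_mech) / nh_Q
        return v

    logs: dict[str, list[float]] = {k: [] for k in
                                    ("V", "E_pot", "E_kin", "T_inst",
                                     "P_inst", "H")}
    log_times: list[float] = []
    kept_frames: list[Frame] = []

    def log_state(step):
        e_kin = _kinetic_energy(vel, masses)
        t_inst = 2.0 * e_kin / (n_dof * R_KJ_PER_MOL_K)
        vol = box ** 3
        p_inst = ((2.0 * e_kin / 3.0 + virial / 3.0)
                  / vol / ATM_A3_TO_KJ_PER_MOL)
        h = e_pot + e_kin + ens.P_target * vol * ATM_A3_TO_KJ_PER_MOL
        logs["V"].append(vol)
        logs["E_pot"].append(e_pot)
        logs["E_kin"].append(e_kin)
        logs["T_inst"].append(t_inst)
        logs["P_inst"].append(p_inst)
        logs["H"].append(h)
        log_times.append(step * dt)

    def keep_frame(step):
        f = Frame(np.mod(pos, box), box, step * dt, vel.copy(),
                  spec.atom_species())
        kept_frames.append(f)

    for step in range(1, n_steps + 1):
        if ens.thermostat == "nose_hoover":
            vel = nh_half(vel)
        # velocity Verlet (with the O step mid-step for BAOAB)
        vel = vel + 0.5 * dt * forces * inv_m
        if ens.thermostat == "langevin":
            pos = pos + 0.5 * dt * vel
            vel = c1 * vel + c2 * rng.normal(size=vel.shape)
            pos = pos + 0.5 * dt * vel
        else:
            pos = pos + dt * vel
        e_pot, forces, virial = forces_at(pos, box)
        vel = vel + 0.5 * dt * forces * inv_m
        if ens.thermostat == "nose_hoover":
            vel = nh_half(vel)

        if not np.all(np.isfinite(pos)) or not np.isfinite(e_pot):
            raise RuntimeError(f"non-finite state at step {step}")

        if barostat is not None and step % ens.barostat_interval == 0:
            pos, box, moved = barostat.attempt(
                pos, box, ff, has_interactions, mol_index, rng)
            if moved:
                e_pot, forces, virial = forces_at(pos, box)

        if remove_com and step % _COM_REMOVAL_STRIDE == 0:
            _remove_com_velocity(vel, masses)

        if step % log_stride == 0:
            log_state(step)
        if traj_stride is not None and step % traj_stride == 0:
            keep_frame(step)

    times = np.array(log_times)
    series = {
        "V": ScalarSeries("V", times, np.array(logs["V"]), "A^3"),
        "E_pot": ScalarSeries("E_pot", times, np.array(logs["E_pot"]), "kJ/mol"),
        "E_kin": ScalarSeries("E_kin", times, np.array(logs["E_kin"]), "kJ/mol"),
        "T_inst": ScalarSeries("T_inst", times, np.array(logs["T_inst"]), "K"),
        "P_inst": ScalarSeries("P_inst", times, np.array(logs["P_inst"]), "atm"),
        "H": ScalarSeries("H", times, np.array(logs["H"]), "kJ/mol"),
    }
    final = Frame(np.mod(pos, box), box, n_steps * dt, vel.copy(),
                  spec.atom_species())
    traj = Trajectory(kept_frames) if kept_frames else None
    return SimulationResult(
        final_frame=final, series=series, trajectory=traj,
        barostat_acceptance=(barostat.acceptance if barostat else None),
        seed=ens.seed, n_steps=n_steps)


def run_gas_phase(spec: SystemSpec, T: float, n_steps: int,
                  dt: float = 0.5, friction: float = 1.0,
                  log_stride: int = 100, seed: int = 0) -> dict[str, ScalarSeries]:
    """Single molecule, no periodic boundaries, no cutoff, Langevin NVT.

    Center-of-mass motion is removed at every log point.  Returns E_pot and
    E_kin series (per molecule, kJ/mol).
    """
    if spec.n_molecules != 1:
        raise ValueError("gas phase runs require a single-molecule spec")
    rng = np.random.default_rng(seed)
    masses = spec.atom_masses()
    ff = ForceField(spec, r_on=10.0, r_off=12.0, periodic=False)
    pos = spec.template.copy()
    vel = maxwell_boltzmann_velocities(masses, T, rng)
    if spec.n_atoms > 1:
        _remove_com_velocity(vel, masses)
    has_interactions = (np.any(ff._eps != 0.0) or np.any(ff._qq != 0.0)
                       or len(ff._bi) > 0)

    gamma = friction / 1000.0
    kT_mech = R_KJ_PER_MOL_K * T / MECH_TO_KJ_PER_MOL
    c1 = np.exp(-gamma * dt)
    c2 = np.sqrt((1.0 - c1 * c1) * kT_mech / masses)[:, None]
    inv_m = 1.0 / (masses[:, None] * MECH_TO_KJ_PER_MOL)

    def forces_at(p):
        if not has_interactions:
            return 0.0, np.zeros_like(p)
        rep = ff.evaluate_raw(p, 1e6)
        return rep.potential, rep.forces

    e_pot, forces = forces_at(pos)
    e_log, k_log, t_log = [], [], []
    for step in range(1, n_steps + 1):
        vel = vel + 0.5 * dt * forces * inv_m
        pos = pos + 0.5 * dt * vel
        vel = c1 * vel + c2 * rng.normal(size=vel.shape)
        pos = pos + 0.5 * dt * vel
        e_pot, forces = forces_at(pos)
        vel = vel + 0.5 * dt * forces * inv_m
        if not np.isfinite(e_pot):
            raise RuntimeError(f"non-finite state at step {step}")
        if step % log_stride == 0:
            if spec.n_atoms > 1:
                _remove_com_velocity(vel, masses)
            e_log.append(e_pot)
            k_log.append(_kinetic_energy(vel, masses))
            t_log.append(step * dt)
    times = np.array(t_log)
    return {
        "E_pot": ScalarSeries("E_pot", times, np.array(e_log), "kJ/mol"),
        "E_kin": ScalarSeries("E_kin", times, np.array(k_log), "kJ/mol"),
    }


def equilibrate(frame: Frame, spec: SystemSpec, ens: EnsembleSpec,
                n_steps: int) -> Frame:
    """Run without logging and return the final frame (velocities kept)."""
    res = run_simulation(frame, spec, ens, n_steps,
                         log_stride=max(n_steps, 1))
    return res.final_frame


def with_new_velocities(frame: Frame, spec: SystemSpec, T: float,
                        seed: int) -> Frame:
    """Copy of ``frame`` with freshly drawn Maxwell–Boltzmann velocities."""
    rng = np.random.default_rng(seed)
    vel = maxwell_boltzmann_velocities(spec.atom_masses(), T, rng)
    _remove_com_velocity(vel, spec.atom_masses())
    f = frame.copy()
    f.velocities = vel
    return f
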