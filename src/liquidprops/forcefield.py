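"""Short-range pair interactions for the toy engine.

Nonbonded pairs (all intermolecular pairs plus intramolecular pairs that are
not directly bonded) interact through a Lennard-Jones potential multiplied by
the CHARMM switching polynomial — S(r) = 1 for r ≤ r_on, a smooth cubic in r²
decaying to 0 at r_off — and, when partial charges are present, a damped
shifted-force Coulomb term whose energy and force both vanish at r_off.
Harmonic bonds U = ½ k (r − r0)² hold the molecule templates together.

Forces are the exact negative gradient of the returned energy; the pair
virial W = Σ r⃗·f⃗ is accumulated for the pressure estimator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numba import njit

from .frames import Frame
from .system import SystemSpec
from .units import COULOMB_KJ_A_PER_MOL

#: Damping parameter of the shifted-force Coulomb interaction, Å⁻¹.
DSF_ALPHA = 0.2


@njit(cache=False)
def _filter_pairs(pos, box, pi, pj, cutoff2):
    """Mask of static pairs within the neighbor-list radius (min image)."""
    keep = np.zeros(pi.shape[0], dtype=np.bool_)
    inv_box = 1.0 / box
    for k in range(pi.shape[0]):
        i = pi[k]
        j = pj[k]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        dx -= box * math.floor(dx * inv_box + 0.5)
        dy -= box * math.floor(dy * inv_box + 0.5)
        dz -= box * math.floor(dz * inv_box + 0.5)
        if dx * dx + dy * dy + dz * dz < cutoff2:
            keep[k] = True
    return keep


@njit(cache=False)
def _pair_kernel(pos, box, pi, pj, sig, eps, qq,
                 r_on, r_off, periodic, use_cutoff, alpha):
    n = pos.shape[0]
    inv_box = 1.0 / box if box > 0 else 0.0
    forces = np.zeros((n, 3))
    energy = 0.0
    virial = 0.0
    r_on2 = r_on * r_on
    r_off2 = r_off * r_off
    denom = (r_off2 - r_on2) ** 3
    # DSF shift constants at the cutoff
    if use_cutoff:
        erfc_rc = math.erfc(alpha * r_off)
        f_shift = (erfc_rc / r_off2
                   + 2.0 * alpha / math.sqrt(math.pi)
                   * math.exp(-alpha * alpha * r_off2) / r_off)
        e_shift = erfc_rc / r_off
    else:
        f_shift = 0.0
        e_shift = 0.0
    for k in range(pi.shape[0]):
        i = pi[k]
        j = pj[k]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        if periodic:
            dx -= box * math.floor(dx * inv_box + 0.5)
            dy -= box * math.floor(dy * inv_box + 0.5)
            dz -= box * math.floor(dz * inv_box + 0.5)
        r2 = dx * dx + dy * dy + dz * dz
        if use_cutoff and r2 >= r_off2:
            continue
        if r2 < 1e-24:  # coincident atoms: signal a blown-up state
            energy = np.inf
            continue
        r = math.sqrt(r2)
        e_k = 0.0
        fmag = 0.0  # force magnitude along r (positive = repulsive), per r
        if eps[k] != 0.0:
            sr2 = sig[k] * sig[k] / r2
            sr6 = sr2 * sr2 * sr2
            sr12 = sr6 * sr6
            u_lj = 4.0 * eps[k] * (sr12 - sr6)
            f_lj = 24.0 * eps[k] * (2.0 * sr12 - sr6) / r
            if use_cutoff and r2 > r_on2:
                a = r_off2 - r2
                b = r_off2 + 2.0 * r2 - 3.0 * r_on2
                s = a * a * b / denom
                ds_dr = 12.0 * r * a * (r_on2 - r2) / denom
                f_lj = f_lj * s - u_lj * ds_dr
                u_lj = u_lj * s
            e_k += u_lj
            fmag += f_lj
        if qq[k] != 0.0:
            c = COULOMB_KJ_A_PER_MOL * qq[k]
            if use_cutoff:
                erfc_r = math.erfc(alpha * r)
                gauss = (2.0 * alpha / math.sqrt(math.pi)
                         * math.exp(-alpha * alpha * r2))
                u_c = c * (erfc_r / r - e_shift + f_shift * (r - r_off))
                f_c = c * (erfc_r / r2 + gauss / r - f_shift)
            else:
                u_c = c / r
                f_c = c / r2
            e_k += u_c
            fmag += f_c
        energy += e_k
        virial += fmag * r
        fx = fmag * dx / r
        fy = fmag * dy / r
        fz = fmag * dz / r
        forces[i, 0] += fx
        forces[i, 1] += fy
        forces[i, 2] += fz
        forces[j, 0] -= fx
        forces[j, 1] -= fy
        forces[j, 2] -= fz
    return energy, forces, virial


@njit(cache=False)
def _bond_kernel(pos, box, bi, bj, bk, br0, periodic):
    n = pos.shape[0]
    forces = np.zeros((n, 3))
    energy = 0.0
    virial = 0.0
    for k in range(bi.shape[0]):
        i = bi[k]
        j = bj[k]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        if periodic:
            dx -= box * math.floor(dx / box + 0.5)
            dy -= box * math.floor(dy / box + 0.5)
            dz -= box * math.floor(dz / box + 0.5)
        r = math.sqrt(dx * dx + dy * dy + dz * dz)
        dr = r - br0[k]
        energy += 0.5 * bk[k] * dr * dr
        fmag = -bk[k] * dr  # along +r̂ on atom i
        virial += fmag * r
        fx = fmag * dx / r
        fy = fmag * dy / r
        fz = fmag * dz / r
        forces[i, 0] += fx
        forces[i, 1] += fy
        forces[i, 2] += fz
        forces[j, 0] -= fx
        forces[j, 1] -= fy
        forces[j, 2] -= fz
    return energy, forces, virial


def _build_pair_table(spec: SystemSpec, intermolecular_only: bool = False):
    """Nonbonded pair arrays with Lorentz–Berthelot combination."""
    n = spec.n_atoms
    m = spec.atoms_per_molecule
    mol = spec.molecule_of_atom()
    bonded = set()
    for b in spec.bonds:
        for imol in range(spec.n_molecules):
            off = imol * m
            bonded.add((off + min(b.i, b.j), off + max(b.i, b.j)))
    ii, jj = np.triu_indices(n, k=1)
    same_mol = mol[ii] == mol[jj]
    keep = np.ones(len(ii), dtype=bool)
    if intermolecular_only:
        keep &= ~same_mol
    else:
        if bonded:
            excl = np.array([(a, b) in bonded
                             for a, b in zip(ii, jj)])
            keep &= ~(same_mol & excl)
    ii, jj = ii[keep], jj[keep]
    ti, tj = ii % m, jj % m
    sig = 0.5 * (spec.lj_sigma[ti] + spec.lj_sigma[tj])
    eps = np.sqrt(spec.lj_epsilon[ti] * spec.lj_epsilon[tj])
    if spec.charges is not None:
        qq = spec.charges[ti] * spec.charges[tj]
    else:
        qq = np.zeros(len(ii))
    return (ii.astype(np.int64), jj.astype(np.int64),
            sig.astype(float), eps.astype(float), qq.astype(float))


@dataclass
class EnergyReport:
    potential: float       # kJ/mol per system
    forces: np.ndarray     # kJ/mol/Å
    virial: float          # kJ/mol, Σ r⃗·f⃗ over pairs and bonds
    pair_energy: float
    bond_energy: float


class ForceField:
    """Evaluates the toy potential for one :class:`SystemSpec`.

    Parameters
    ----------
    r_on, r_off : switching window in Å; ``periodic=False`` disables both
        the cutoff and the minimum-image convention (gas phase).
    """

    #: extra neighbor-list radius beyond r_off, Å
    skin: float = 1.0

    def __init__(self, spec: SystemSpec, r_on: float = 10.0,
                 r_off: float = 12.0, periodic: bool = True,
                 dsf_alpha: float = DSF_ALPHA,
                 use_neighbor_list: bool = True):
        if periodic and not (0.0 < r_on < r_off):
            raise ValueError("need 0 < r_on < r_off")
        self.spec = spec
        self.r_on = float(r_on)
        self.r_off = float(r_off)
        self.periodic = bool(periodic)
        self.dsf_alpha = float(dsf_alpha)
        self.use_neighbor_list = bool(use_neighbor_list) and self.periodic
        (self._pi, self._pj, self._sig, self._eps,
         self._qq) = _build_pair_table(spec)
        self._nl_ref_pos: np.ndarray | None = None
        self._nl_box: float = -1.0
        self._nl_arrays = (self._pi, self._pj, self._sig, self._eps, self._qq)
        bi, bj, bk, br0 = [], [], [], []
        for imol in range(spec.n_molecules):
            off = imol * spec.atoms_per_molecule
            for b in spec.bonds:
                bi.append(off + b.i)
                bj.append(off + b.j)
                bk.append(b.k)
                br0.append(b.r0)
        self._bi = np.array(bi, dtype=np.int64)
        self._bj = np.array(bj, dtype=np.int64)
        self._bk = np.array(bk, dtype=float)
        self._br0 = np.array(br0, dtype=float)

    def evaluate(self, frame: Frame) -> EnergyReport:
        return self.evaluate_raw(frame.positions, frame.box_length)

    def evaluate_raw(self, positions: np.ndarray, box_length: float) -> EnergyReport:
        """Same as :meth:`evaluate` but on bare arrays (hot path)."""
        if self.periodic and self.r_off >= box_length / 2.0:
            raise ValueError(
                f"r_off = {self.r_off} Å >= box_length/2 = "
                f"{box_length / 2.0:.3f} Å: minimum-image convention "
                "violated")
        pos = np.ascontiguousarray(positions, dtype=float)
        if self.use_neighbor_list:
            pi, pj, sig, eps, qq = self._neighbor_arrays(pos, float(box_length))
        else:
            pi, pj, sig, eps, qq = (self._pi, self._pj, self._sig,
                                    self._eps, self._qq)
        e_pair, f_pair, w_pair = _pair_kernel(
            pos, float(box_length), pi, pj, sig, eps, qq,
            self.r_on, self.r_off, self.periodic, self.periodic,
            self.dsf_alpha)
        if f_pair.shape[0] != pos.shape[0]:
            raise AssertionError("kernel force shape mismatch")
        if len(self._bi):
            e_bond, f_bond, w_bond = _bond_kernel(
                pos, float(box_length), self._bi, self._bj,
                self._bk, self._br0, self.periodic)
        else:
            e_bond, w_bond = 0.0, 0.0
            f_bond = np.zeros_like(f_pair)
        return EnergyReport(
            potential=float(e_pair + e_bond),
            forces=f_pair + f_bond,
            virial=float(w_pair + w_bond),
            pair_energy=float(e_pair),
            bond_energy=float(e_bond),
        )

    def _neighbor_arrays(self, pos: np.ndarray, box: float):
        """Verlet-list pair subset; rebuilt when any atom moved > skin/2
        since the last build, or the box changed."""
        rebuild = (self._nl_ref_pos is None or box != self._nl_box
                   or pos.shape != self._nl_ref_pos.shape)
        if not rebuild:
            disp2 = np.max(np.sum((pos - self._nl_ref_pos) ** 2, axis=1))
            rebuild = disp2 > (0.5 * self.skin) ** 2
        if rebuild:
            cutoff = self.r_off + self.skin
            keep = _filter_pairs(pos, box, self._pi, self._pj, cutoff * cutoff)
            self._nl_arrays = (self._pi[keep], self._pj[keep],
                               self._sig[keep], self._eps[keep],
                               self._qq[keep])
            self._nl_ref_pos = pos.copy()
            self._nl_box = box
        return self._nl_arrays

    def intermolecular_energy(self, frame: Frame) -> float:
        """Pair energy restricted to intermolecular pairs (ΔH_vap oracle)."""
        pi, pj, sig, eps, qq = _build_pair_table(
            self.spec, intermolecular_only=True)
        pos = np.ascontiguousarray(frame.positions, dtype=float)
        e, _, _ = _pair_kernel(pos, float(frame.box_length), pi, pj, sig,
                               eps, qq, self.r_on, self.r_off,
                               self.periodic, self.periodic, self.dsf_alpha)
        return float(e)


def energy_forces(frame: Frame, spec: SystemSpec, r_on: float,
                  r_off: float, periodic: bool = True):
    """One-shot (potential energy, forces) evaluation; see :class:`ForceField`."""
    ff = ForceField(spec, r_on, r_off, periodic=periodic)
    rep = ff.evaluate(frame)
    return rep.potential, rep.forces
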