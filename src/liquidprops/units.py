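"""Internal unit system and physical constants.

Internal units are Å (length), fs (time), amu (mass), K (temperature) and
atm (pressure).  Energies are bookkept *per mole of systems* in kJ/mol, which
makes the amu/Å/fs mechanical energy unit exactly 10^4 kJ/mol (because
1 amu = 1 g/mol by definition).  In this bookkeeping the "per particle"
Boltzmann constant kB·T is numerically R·T in kJ/mol, so the fluctuation
formulas can be written once with R and remain correct whichever way the
energies are read.
"""

from __future__ import annotations

from dataclasses import dataclass

#: Avogadro constant, 1/mol (CODATA 2018, exact).
AVOGADRO = 6.02214076e23

#: Boltzmann constant, J/K per particle (exact).
KB_J_PER_K = 1.380649e-23

#: Molar gas constant, kJ/(mol K).
R_KJ_PER_MOL_K = KB_J_PER_K * AVOGADRO / 1000.0  # 8.31446261815324e-3

#: Molar gas constant, J/(mol K).
R_J_PER_MOL_K = R_KJ_PER_MOL_K * 1000.0

#: 1 amu Å²/fs² expressed in kJ/mol (exactly 1e4 because amu = g/mol).
MECH_TO_KJ_PER_MOL = 1.0e4

#: 1 atm Å³ expressed in kJ/mol.
ATM_A3_TO_KJ_PER_MOL = 101325.0 * 1e-30 * AVOGADRO / 1000.0

#: Coulomb constant e²/(4π ε0), in kJ Å / mol (CODATA e and ε0).
COULOMB_KJ_A_PER_MOL = 1389.35457644382

#: 1 Å²/fs expressed in cm²/s.
A2_PER_FS_TO_CM2_PER_S = 0.1

#: 1 amu expressed in grams.
AMU_TO_G = 1.0 / AVOGADRO

#: 1 atm⁻¹ expressed in bar⁻¹ (1 atm = 1.01325 bar).
PER_ATM_TO_PER_BAR = 1.0 / 1.01325


@dataclass(frozen=True)
class UnitSystem:
    """The package-wide unit conventions, exposed as one object.

    Attributes
    ----------
    kB : float
        Boltzmann constant in J/K (per particle).
    R : float
        Gas constant in kJ/(mol K) — the "per particle" energy constant in
        the internal per-mole energy bookkeeping.
    pv_to_energy : float
        Conversion factor from atm·Å³ to kJ/mol.
    """

    length: str = "angstrom"
    time: str = "fs"
    energy: str = "kJ/mol"
    temperature: str = "K"
    pressure: str = "atm"
    kB: float = KB_J_PER_K
    R: float = R_KJ_PER_MOL_K
    pv_to_energy: float = ATM_A3_TO_KJ_PER_MOL

    def pv_energy(self, pressure_atm: float, volume_A3: float) -> float:
        """P·V in kJ/mol for P in atm and V in Å³."""
        return pressure_atm * volume_A3 * self.pv_to_energy

    def energy_to_pv(self, energy_kj_mol: float) -> float:
        """Inverse of :meth:`pv_energy` at unit pressure: kJ/mol → atm·Å³."""
        return energy_kj_mol / self.pv_to_energy


UNITS = UnitSystem()


def kinetic_temperature(e_kin_kj_mol: float, n_dof: int) -> float:
    """Instantaneous kinetic temperature from the kinetic energy.

    T_inst = 2 E_kin / (n_dof kB), with E_kin per mole of systems in kJ/mol
    so kB appears as R.
    """
    if n_dof <= 0:
        raise ValueError("n_dof must be positive")
    return 2.0 * e_kin_kj_mol / (n_dof * R_KJ_PER_MOL_K)


def density_g_cm3(total_mass_amu: float, volume_A3: float) -> float:
    """Mass density in g/cm³ from a mass in amu and a volume in Å³."""
    return total_mass_amu * AMU_TO_G / (volume_A3 * 1e-24)


def volume_for_density(total_mass_amu: float, density_g_cm3_: float) -> float:
    """Box volume in Å³ that gives the requested mass density."""
    if density_g_cm3_ <= 0:
        raise ValueError("density must be positive")
    return total_mass_amu * AMU_TO_G / density_g_cm3_ * 1e24
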