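"""Toy-liquid system definitions and the lattice system builder.

A :class:`SystemSpec` describes n identical flexible molecules: per-atom
masses, Lennard-Jones parameters and optional partial charges, plus harmonic
bonds within the molecule template.  :func:`build_system` places the
molecules on a cubic lattice with random orientations in a box sized to hit
a requested mass density exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .frames import Frame
from .units import volume_for_density


@dataclass
class Bond:
    """Harmonic bond U = ½ k (r − r0)² between template atoms i, j."""
    i: int
    j: int
    k: float   # kJ/mol/Å²
    r0: float  # Å


@dataclass
class SystemSpec:
    n_molecules: int
    atoms_per_molecule: int
    masses: np.ndarray                 # amu, per template atom
    lj_sigma: np.ndarray               # Å, per template atom
    lj_epsilon: np.ndarray             # kJ/mol, per template atom
    charges: np.ndarray | None = None  # e, per template atom
    bonds: list[Bond] = field(default_factory=list)
    template: np.ndarray | None = None  # Å, reference intramolecular geometry
    species: list[str] = field(default_factory=list)
    name: str = "toy"

    def __post_init__(self) -> None:
        m = self.atoms_per_molecule
        self.masses = np.asarray(self.masses, dtype=float)
        self.lj_sigma = np.asarray(self.lj_sigma, dtype=float)
        self.lj_epsilon = np.asarray(self.lj_epsilon, dtype=float)
        for arr, label in ((self.masses, "masses"),
                           (self.lj_sigma, "lj_sigma"),
                           (self.lj_epsilon, "lj_epsilon")):
            if arr.shape != (m,):
                raise ValueError(f"{label} must have one entry per template atom")
        if np.any(self.masses <= 0):
            raise ValueError("masses must be positive")
        if np.any(self.lj_sigma <= 0):
            raise ValueError("lj_sigma must be positive")
        if self.charges is not None:
            self.charges = np.asarray(self.charges, dtype=float)
            if self.charges.shape != (m,):
                raise ValueError("charges must have one entry per template atom")
        for b in self.bonds:
            if not (0 <= b.i < m and 0 <= b.j < m and b.i != b.j):
                raise ValueError(f"bond ({b.i},{b.j}) references invalid atoms")
        if self.template is None:
            self.template = _default_template(m, self.bonds)
        else:
            self.template = np.asarray(self.template, dtype=float)
            if self.template.shape != (m, 3):
                raise ValueError("template must be (atoms_per_molecule, 3)")
        if not self.species:
            self.species = [f"X{i}" for i in range(m)] if m > 1 else ["X"]
        if self.n_molecules < 1:
            raise ValueError("n_molecules must be >= 1")

    @property
    def n_atoms(self) -> int:
        return self.n_molecules * self.atoms_per_molecule

    @property
    def molecule_mass(self) -> float:
        return float(self.masses.sum())

    @property
    def total_mass(self) -> float:
        return self.molecule_mass * self.n_molecules

    def atom_masses(self) -> np.ndarray:
        return np.tile(self.masses, self.n_molecules)

    def atom_species(self) -> list[str]:
        return list(self.species) * self.n_molecules

    def molecule_of_atom(self) -> np.ndarray:
        return np.repeat(np.arange(self.n_molecules), self.atoms_per_molecule)


def _default_template(m: int, bonds: list[Bond]) -> np.ndarray:
    """A plausible compact geometry honoring bond rest lengths when easy."""
    if m == 1:
        return np.zeros((1, 3))
    # place atoms on a short chain at mean bond length
    r0 = np.mean([b.r0 for b in bonds]) if bonds else 1.5
    t = np.zeros((m, 3))
    for i in range(1, m):
        t[i] = t[i - 1] + np.array([r0, 0.15 * r0 * ((-1) ** i), 0.0])
    return t - t.mean(axis=0)


def build_system(spec: SystemSpec, density: float,
                 seed: int = 0, min_dist_factor: float = 0.8) -> Frame:
    """Place molecules on a cubic lattice at the requested mass density.

    The box length is set so that the mass density equals ``density`` (g/cm³)
    exactly; molecule templates get independent random orientations.  Raises
    if any intermolecular atom pair comes closer than
    ``min_dist_factor × min(σ_i, σ_j)``.
    """
    if density <= 0:
        raise ValueError("density must be positive")
    volume = volume_for_density(spec.total_mass, density)
    box = volume ** (1.0 / 3.0)
    n = spec.n_molecules
    n_side = int(np.ceil(n ** (1.0 / 3.0)))
    spacing = box / n_side
    rng = np.random.default_rng(seed)

    sites = []
    for a in range(n_side):
        for b in range(n_side):
            for c in range(n_side):
                sites.append((a, b, c))
    sites = np.array(sites[:n], dtype=float)
    centers = (sites + 0.5) * spacing

    pos = np.empty((spec.n_atoms, 3))
    m = spec.atoms_per_molecule
    template = spec.template - np.average(spec.template, axis=0,
                                          weights=spec.masses)
    # retry orientations until the per-pair distance floor 0.8·σ_ij holds
    for attempt in range(50):
        for i in range(n):
            rot = _random_rotation(rng)
            pos[i * m:(i + 1) * m] = centers[i] + template @ rot.T
        frame = Frame(pos.copy(), box, 0.0,
                      species=spec.atom_species()).wrapped()
        if n == 1:
            return frame
        ratio, pair, dmin = _min_scaled_distance(frame, spec)
        if ratio > min_dist_factor:
            return frame
    raise ValueError(
        f"density {density} g/cm³ too high: intermolecular atom pair "
        f"{pair} at {dmin:.3f} Å violates the {min_dist_factor}·σ floor "
        "after 50 orientation attempts")


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix (quaternion method)."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


def _min_scaled_distance(frame: Frame, spec: SystemSpec):
    """min over intermolecular pairs of d_ij / σ_ij (Lorentz combined σ)."""
    from .frames import minimum_image
    mol = spec.molecule_of_atom()
    pos = frame.positions
    n = frame.n_atoms
    sig_atom = np.tile(spec.lj_sigma, spec.n_molecules)
    best, pair, dmin = np.inf, (0, 0), np.inf
    # O(N²) check; builder systems stay small
    for i in range(n - 1):
        dr = minimum_image(pos[i + 1:] - pos[i], frame.box_length)
        d = np.linalg.norm(dr, axis=1)
        sig_ij = 0.5 * (sig_atom[i] + sig_atom[i + 1:])
        ratio = np.where(mol[i + 1:] != mol[i], d / sig_ij, np.inf)
        j_rel = int(np.argmin(ratio))
        if ratio[j_rel] < best:
            best = float(ratio[j_rel])
            pair = (i, i + 1 + j_rel)
            dmin = float(d[j_rel])
    return best, pair, dmin


# ---------------------------------------------------------------------------
# Catalog of ready-made specs
# ---------------------------------------------------------------------------

def lj_fluid(n: int = 108, sigma: float = 3.4, epsilon: float = 0.996,
             mass: float = 39.948) -> SystemSpec:
    """Monatomic Lennard-Jones fluid (argon-like defaults)."""
    return SystemSpec(n, 1, [mass], [sigma], [epsilon],
                      species=["Ar"], name=f"lj{n}")


def ideal_gas(n: int = 200, mass: float = 39.948) -> SystemSpec:
    """Non-interacting particles (ε = 0): the exact-closed-form benchmark."""
    return SystemSpec(n, 1, [mass], [3.4], [0.0],
                      species=["Ar"], name=f"ideal{n}")


def polar_liquid(n: int = 64) -> SystemSpec:
    """Flexible 3-site water-like polar liquid.

    Geometry is triangulated with three stiff bonds (O-H, O-H, H-H) so the
    bent shape survives without explicit angle terms; charges -0.8/+0.4 e
    give a point dipole comparable to simple 3-site water models.
    """
    r_oh = 1.0
    theta = np.deg2rad(109.47)
    r_hh = 2.0 * r_oh * np.sin(theta / 2.0)
    template = np.array([
        [0.0, 0.0, 0.0],
        [r_oh, 0.0, 0.0],
        [r_oh * np.cos(theta), r_oh * np.sin(theta), 0.0],
    ])
    return SystemSpec(
        n_molecules=n, atoms_per_molecule=3,
        masses=[15.999, 1.008, 1.008],
        lj_sigma=[3.166, 1.0, 1.0],
        lj_epsilon=[0.650, 0.066, 0.066],
        charges=[-0.8, 0.4, 0.4],
        bonds=[Bond(0, 1, 2000.0, r_oh), Bond(0, 2, 2000.0, r_oh),
               Bond(1, 2, 1000.0, r_hh)],
        template=template,
        species=["O", "H", "H"],
        name=f"polar{n}",
    )


def harmonic_diatomic(k: float = 1000.0, r0: float = 1.2,
                      masses=(12.011, 12.011)) -> SystemSpec:
    """Single harmonic diatomic, the gas-phase equipartition benchmark."""
    return SystemSpec(1, 2, list(masses), [3.0, 3.0], [0.4, 0.4],
                      bonds=[Bond(0, 1, k, r0)],
                      template=np.array([[0.0, 0.0, 0.0], [r0, 0.0, 0.0]]),
                      species=["C", "C"], name="diatomic")


#: Published simulation-system sizes for the six liquids studied
#: (molecule counts and atoms per molecule).  The NMA row of the source
#: table prints 1764 total atoms, inconsistent with 146 × 12 = 1752.
TABLE_SYSTEMS = {
    "water": (572, 3),
    "methanol": (323, 6),
    "acetone": (178, 10),
    "benzene": (130, 12),
    "n-hexane": (98, 20),
    "nma": (146, 12),
}


def table_system(name: str) -> SystemSpec:
    """Generic flexible-molecule spec with the published size for `name`."""
    n, m = TABLE_SYSTEMS[name]
    bonds = [Bond(i, i + 1, 1500.0, 1.4) for i in range(m - 1)]
    return SystemSpec(n, m, [12.0] * m, [3.2] * m, [0.3] * m,
                      bonds=bonds, name=name)
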