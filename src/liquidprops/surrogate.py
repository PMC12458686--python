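"""Gaussian surrogate for NPT (volume, enthalpy) fluctuations.

Inverts the fluctuation estimators: given target isothermal compressibility
κ, isobaric heat capacity C_p and thermal expansion coefficient α at a state
point (⟨V⟩, T, P, N molecules), draws i.i.d. bivariate-normal (V, H) samples
whose population moments are

    Var(V)   = κ kB T ⟨V⟩
    Var(H)   = C_p N R T²      (per-mole bookkeeping, H per system in kJ/mol)
    Cov(V,H) = α R T² ⟨V⟩

so the estimators in :mod:`liquidprops.thermo` recover the targets up to
Monte-Carlo error.  The surrogate reproduces the marginal NPT fluctuation
statistics only — it carries no serial correlation and no microscopic
structure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .series import ScalarSeries
from .units import ATM_A3_TO_KJ_PER_MOL, R_KJ_PER_MOL_K


@dataclass
class SurrogateSpec:
    mean_V: float          # Å³
    T: float               # K
    P: float = 1.0         # atm
    n_molecules: int = 1
    target_kappa: float = 1e-5   # atm⁻¹
    target_Cp: float = 75.0      # J/(mol K)
    target_alpha: float = 2e-4   # K⁻¹  (may be negative)
    n_samples: int = 100_000
    seed: int = 0
    mean_H: float = 0.0          # kJ/mol; offset only, estimators ignore it
    stride_fs: float = 50.0

    def covariance(self) -> tuple[float, float, float]:
        """(Var(V) Å⁶, Var(H) (kJ/mol)², Cov(V,H) Å³·kJ/mol)."""
        if self.mean_V <= 0 or self.T <= 0 or self.n_molecules < 1:
            raise ValueError("mean_V, T must be positive; n_molecules >= 1")
        if self.target_kappa <= 0 or self.target_Cp <= 0:
            raise ValueError("target_kappa and target_Cp must be positive")
        kT_kj = R_KJ_PER_MOL_K * self.T              # per-particle ≡ R·T
        kT_atmA3 = kT_kj / ATM_A3_TO_KJ_PER_MOL
        var_V = self.target_kappa * kT_atmA3 * self.mean_V
        cp_kj = self.target_Cp / 1000.0
        var_H = cp_kj * self.n_molecules * R_KJ_PER_MOL_K * self.T ** 2
        cov_VH = self.target_alpha * R_KJ_PER_MOL_K * self.T ** 2 * self.mean_V
        return var_V, var_H, cov_VH


def gaussian_surrogate(spec: SurrogateSpec) -> tuple[ScalarSeries, ScalarSeries]:
    """Draw the (V, H) series; raises if the targets violate Cauchy–Schwarz."""
    var_V, var_H, cov_VH = spec.covariance()
    if cov_VH ** 2 > var_V * var_H:
        raise ValueError(
            f"covariance targets violate Cauchy–Schwarz: Cov(V,H)² = "
            f"{cov_VH ** 2:.4g} > Var(V)·Var(H) = {var_V * var_H:.4g}")
    rng = np.random.default_rng(spec.seed)
    mean = np.array([spec.mean_V, spec.mean_H])
    cov = np.array([[var_V, cov_VH], [cov_VH, var_H]])
    samples = rng.multivariate_normal(mean, cov, size=spec.n_samples,
                                      method="eigh")
    times = np.arange(spec.n_samples) * spec.stride_fs
    v = ScalarSeries("V", times, samples[:, 0], "A^3")
    h = ScalarSeries("H", times, samples[:, 1], "kJ/mol")
    return v, h
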