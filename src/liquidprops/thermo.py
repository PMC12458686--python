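"""Fluctuation-based thermodynamic property estimators.

From NPT observable series these compute the heat of vaporization
ΔH_vap = ⟨E_gas⟩ − ⟨E_liquid⟩/N + RT, the isothermal compressibility
κ = ⟨ΔV²⟩ / (kB T ⟨V⟩), the isobaric heat capacity
C_p = ⟨ΔH²⟩ / (N R T²), the thermal expansion coefficient
α = Cov(V, H) / (R T² ⟨V⟩) and the mean density ρ̂ = ⟨m/V⟩, plus the
signed relative error against an experimental reference, cumulative
convergence series, and inter-repeat statistics.

Conventions: fluctuations are population (biased) variances/covariances,
energies are bookkept per mole of systems in kJ/mol (so the per-particle
kB appears as R throughout), N is the number of molecules, and C_p is
reported per mole of molecules in J/(mol K).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .properties import PropertyEstimate
from .series import ScalarSeries, check_aligned, series_stats
from .units import (ATM_A3_TO_KJ_PER_MOL, PER_ATM_TO_PER_BAR,
                    R_KJ_PER_MOL_K, density_g_cm3)


@dataclass
class ThermoInputs:
    """Bundle of the series and state-point data the estimators need."""

    n_molecules: int
    T: float
    P_ext: float = 1.0
    total_mass: float = 0.0            # amu
    V: ScalarSeries | None = None
    E_liquid: ScalarSeries | None = None   # per system, kJ/mol
    E_gas: ScalarSeries | None = None      # per single molecule, kJ/mol
    H: ScalarSeries | None = None          # per system, kJ/mol
    x_exp: dict | None = None

    def __post_init__(self) -> None:
        if self.n_molecules < 1:
            raise ValueError("n_molecules must be >= 1")
        if self.T <= 0:
            raise ValueError("T must be positive")


def _pop_cov(x: np.ndarray, y: np.ndarray) -> float:
    return float(np.mean(x * y) - np.mean(x) * np.mean(y))


def enthalpy_series(E_pot: ScalarSeries, E_kin: ScalarSeries,
                    V: ScalarSeries, P_ext: float) -> ScalarSeries:
    """H_i = E_pot,i + E_kin,i + P_ext·V_i (PV converted to kJ/mol)."""
    check_aligned(E_pot, E_kin, V)
    h = (E_pot.values + E_kin.values
         + P_ext * V.values * ATM_A3_TO_KJ_PER_MOL)
    return ScalarSeries("H", E_pot.times, h, "kJ/mol")


def heat_of_vaporization(inputs: ThermoInputs) -> PropertyEstimate:
    """ΔH_vap = ⟨E_gas⟩ − ⟨E_liquid⟩/N + RT, in kJ/mol.

    E_gas is the energy of one molecule in the gas phase; E_liquid the
    energy of the N-molecule liquid system.  Potential energies are the
    intended inputs: kinetic terms of identical classical flexible molecules
    cancel between the phases, which makes the interaction-free limit
    exactly RT.
    """
    if inputs.E_gas is None or inputs.E_liquid is None:
        raise ValueError("heat_of_vaporization needs E_gas and E_liquid series")
    sg = series_stats(inputs.E_gas)
    sl = series_stats(inputs.E_liquid)
    n = inputs.n_molecules
    value = sg.mean - sl.mean / n + R_KJ_PER_MOL_K * inputs.T
    err = float(np.hypot(sg.std_error, sl.std_error / n))
    return PropertyEstimate(value, "dHvap", "kJ/mol", std_error=err,
                            meta={"T": inputs.T, "n_molecules": n})


def isothermal_compressibility(V: ScalarSeries, T: float) -> PropertyEstimate:
    """κ = ⟨ΔV²⟩ / (kB T ⟨V⟩), reported in atm⁻¹."""
    if len(V) < 2:
        raise ValueError("need at least 2 volume samples")
    if T <= 0:
        raise ValueError("T must be positive")
    st = series_stats(V)
    kT_atmA3 = R_KJ_PER_MOL_K * T / ATM_A3_TO_KJ_PER_MOL
    kappa = st.variance / (kT_atmA3 * st.mean)
    return PropertyEstimate(kappa, "kappa", "1/atm",
                            meta={"T": T, "per_bar": kappa * PER_ATM_TO_PER_BAR})


def heat_capacity(H: ScalarSeries, n_molecules: int, T: float) -> PropertyEstimate:
    """C_p = ⟨ΔH²⟩ / (N R T²), per mole of molecules, in J/(mol K)."""
    if len(H) < 2:
        raise ValueError("need at least 2 enthalpy samples")
    st = series_stats(H)
    cp_kj = st.variance / (n_molecules * R_KJ_PER_MOL_K * T ** 2)
    return PropertyEstimate(cp_kj * 1000.0, "Cp", "J/(mol K)",
                            meta={"T": T, "n_molecules": n_molecules})


def thermal_expansion(V: ScalarSeries, H: ScalarSeries, T: float) -> PropertyEstimate:
    """α = Cov(V, H) / (R T² ⟨V⟩), in K⁻¹; V and H must be time-aligned."""
    check_aligned(V, H)
    cov = _pop_cov(V.values, H.values)
    alpha = cov / (R_KJ_PER_MOL_K * T ** 2 * float(np.mean(V.values)))
    return PropertyEstimate(alpha, "alpha", "1/K", meta={"T": T})


def mean_density(V: ScalarSeries, total_mass: float) -> PropertyEstimate:
    """ρ̂ = ⟨m/V_i⟩ in g/cm³ (mean of instantaneous densities).

    The alternative convention m/⟨V⟩ is reported in ``meta`` — the two differ
    at second order in the relative volume fluctuations.
    """
    if total_mass <= 0:
        raise ValueError("total_mass must be positive")
    inst = np.array([density_g_cm3(total_mass, v) for v in V.values])
    rho_of_mean = density_g_cm3(total_mass, float(np.mean(V.values)))
    return PropertyEstimate(float(np.mean(inst)), "rho", "g/cm^3",
                            meta={"mass_over_mean_V": rho_of_mean})


def relative_error(x_hat: float, x_exp: float) -> float:
    """Signed relative error (x̂ − x_exp) / x_exp."""
    if x_exp == 0:
        raise ValueError("reference value must be nonzero")
    return (x_hat - x_exp) / x_exp


def cumulative_series(estimator: Callable[..., float], window: float,
                      *series: ScalarSeries) -> ScalarSeries:
    """Convergence monitor: the estimator recomputed on growing prefixes.

    The value at time t is ``estimator`` applied to all samples in [0, t],
    evaluated at t = window, 2·window, … (``window`` in fs, a multiple of
    the logging stride).  ``estimator`` receives one prefix ScalarSeries per
    input series.
    """
    s0 = series[0]
    if len(series) > 1:
        check_aligned(*series)
    stride = s0.stride
    if window < stride:
        raise ValueError("window must be at least the logging stride")
    if abs(window / stride - round(window / stride)) > 1e-9:
        raise ValueError("window must be a multiple of the logging stride")
    t0 = s0.times[0]
    out_t, out_v = [], []
    t_end = s0.times[-1]
    k = 1
    while True:
        t = t0 + k * window - stride  # prefix of k·(window/stride) samples
        if t > t_end + 1e-9:
            break
        n = int(round(window / stride)) * k
        prefixes = [ScalarSeries(s.name, s.times[:n], s.values[:n], s.units)
                    for s in series]
        out_t.append(s0.times[n - 1])
        out_v.append(estimator(*prefixes))
        k += 1
    return ScalarSeries("cumulative", np.array(out_t), np.array(out_v))


def cumulative_mean(s: ScalarSeries, window: float) -> ScalarSeries:
    return cumulative_series(lambda p: p.mean(), window, s)


def repeat_statistics(estimates: Sequence[PropertyEstimate]) -> PropertyEstimate:
    """Mean and inter-run sample standard deviation of repeated estimates."""
    if len(estimates) < 2:
        raise ValueError("need at least 2 repeats")
    kinds = {e.property_kind for e in estimates}
    if len(kinds) > 1:
        raise ValueError(f"mixed property kinds: {sorted(kinds)}")
    units = {e.units for e in estimates}
    if len(units) > 1:
        raise ValueError(f"mixed units: {sorted(units)}")
    values = np.array([e.value for e in estimates])
    return PropertyEstimate(
        float(np.mean(values)), estimates[0].property_kind,
        estimates[0].units,
        std_error=float(np.std(values, ddof=1)),
        n_repeats=len(estimates),
        meta={"per_run_values": values.tolist()})
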