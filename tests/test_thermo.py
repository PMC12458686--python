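"""Fluctuation estimators: closed forms, unit oracles, convergence."""

import numpy as np
import pytest

from liquidprops.properties import PropertyEstimate
from liquidprops.series import ScalarSeries
from liquidprops.thermo import (ThermoInputs, cumulative_mean,
                                cumulative_series, enthalpy_series,
                                heat_capacity, heat_of_vaporization,
                                isothermal_compressibility, mean_density,
                                relative_error, repeat_statistics,
                                thermal_expansion)
from liquidprops.units import (ATM_A3_TO_KJ_PER_MOL, AMU_TO_G,
                               R_KJ_PER_MOL_K)


def _series(values, name="x", stride=50.0):
    values = np.asarray(values, dtype=float)
    return ScalarSeries(name, np.arange(len(values)) * stride, values)


class TestEnthalpy:
    def test_zero_pressure_reduces_to_total_energy(self):
        e_pot = _series([1.0, 2.0, 3.0])
        e_kin = _series([0.5, 0.5, 0.5])
        v = _series([1000.0, 1000.0, 1000.0])
        h = enthalpy_series(e_pot, e_kin, v, 0.0)
        np.testing.assert_allclose(h.values, [1.5, 2.5, 3.5])

    def test_pv_term_unit_conversion(self):
        """1 atm · 1000 Å³ = 101325 Pa · 1e-27 m³ · N_A / 1000 kJ/mol."""
        e = _series([10.0, 10.0])
        v = _series([1000.0, 1000.0])
        h = enthalpy_series(e, _series([0.0, 0.0]), v, 1.0)
        hand = 10.0 + 101325.0 * 1e-27 * 6.02214076e23 / 1000.0
        assert h.values[0] == pytest.approx(hand, rel=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            enthalpy_series(_series([1.0, 2.0]), _series([1.0]),
                            _series([1.0, 2.0]), 1.0)


class TestHeatOfVaporization:
    def test_stated_means_arithmetic(self):
        """⟨E_gas⟩ = 5, ⟨E_liq⟩/n = −30 at 300 K → 35 + RT kJ/mol."""
        inp = ThermoInputs(n_molecules=10, T=300.0,
                           E_gas=_series([5.0] * 4),
                           E_liquid=_series([-300.0] * 4))
        est = heat_of_vaporization(inp)
        assert est.value == pytest.approx(35.0 + R_KJ_PER_MOL_K * 300.0,
                                          rel=1e-12)

    def test_interaction_free_limit_is_rt(self):
        """E_gas ≡ E_liquid/n makes ΔH_vap exactly RT ≈ 2.494 kJ/mol."""
        rng = np.random.default_rng(0)
        e = rng.normal(-10.0, 1.0, 500)
        inp = ThermoInputs(n_molecules=5, T=300.0,
                           E_gas=_series(e),
                           E_liquid=_series(5 * e))
        est = heat_of_vaporization(inp)
        assert est.value == pytest.approx(R_KJ_PER_MOL_K * 300.0, rel=1e-10)
        assert est.value == pytest.approx(2.494, abs=2e-3)

    def test_missing_gas_series_rejected(self):
        with pytest.raises(ValueError, match="E_gas"):
            heat_of_vaporization(ThermoInputs(
                n_molecules=5, T=300.0, E_liquid=_series([1.0, 2.0])))


class TestCompressibility:
    def test_constant_volume_gives_zero(self):
        assert isothermal_compressibility(_series([500.0] * 10), 300.0
                                          ).value == 0.0

    def test_hand_computed_value(self):
        """κ from a two-point series against a hand unit conversion."""
        v = _series([900.0, 1100.0])  # mean 1000, population var 1e4
        kappa = isothermal_compressibility(v, 300.0).value
        kT_atmA3 = R_KJ_PER_MOL_K * 300.0 / ATM_A3_TO_KJ_PER_MOL
        assert kappa == pytest.approx(1e4 / (kT_atmA3 * 1000.0), rel=1e-12)


class TestHeatCapacity:
    def test_constant_enthalpy_gives_zero(self):
        assert heat_capacity(_series([42.0] * 5), 10, 300.0).value == 0.0

    def test_per_mole_reporting(self):
        h = _series([0.0, 2.0])  # var = 1 (kJ/mol)²
        cp = heat_capacity(h, 4, 250.0)
        assert cp.units == "J/(mol K)"
        assert cp.value == pytest.approx(
            1.0 / (4 * R_KJ_PER_MOL_K * 250.0 ** 2) * 1000.0, rel=1e-12)


class TestThermalExpansion:
    def test_unpaired_series_rejected(self):
        v = _series([1.0, 2.0, 3.0])
        h = ScalarSeries("H", np.arange(3) * 50.0 + 25.0, np.ones(3))
        with pytest.raises(ValueError, match="aligned"):
            thermal_expansion(v, h, 300.0)

    def test_hand_computed_covariance(self):
        v = _series([900.0, 1100.0])
        h = _series([1.0, 3.0])   # Cov = 100
        alpha = thermal_expansion(v, h, 300.0).value
        assert alpha == pytest.approx(
            100.0 / (R_KJ_PER_MOL_K * 300.0 ** 2 * 1000.0), rel=1e-12)


class TestDensity:
    def test_water_box_hand_computation(self):
        """572 water-mass molecules in the published 25.80 Å NVT box."""
        mass = 572 * (15.999 + 2 * 1.008)
        v = _series([25.80 ** 3] * 3)
        rho = mean_density(v, mass).value
        hand = mass * AMU_TO_G / (25.80 ** 3 * 1e-24)
        assert rho == pytest.approx(hand, rel=1e-9)
        assert rho == pytest.approx(0.996, abs=0.02)  # near 1 g/cm³

    def test_volume_doubling_halves_density(self):
        v1 = mean_density(_series([1000.0] * 3), 100.0).value
        v2 = mean_density(_series([2000.0] * 3), 100.0).value
        assert v1 == pytest.approx(2 * v2, rel=1e-12)

    def test_constant_series_equals_single_frame(self):
        a = mean_density(_series([1234.0, 1234.0]), 50.0).value
        b = mean_density(_series([1234.0]), 50.0).value
        assert a == b

    def test_both_conventions_reported(self):
        v = _series([900.0, 1100.0])
        est = mean_density(v, 100.0)
        assert est.meta["mass_over_mean_V"] < est.value  # Jensen


class TestRelativeError:
    @pytest.mark.parametrize("x_hat,x_exp,expected", [
        (1.0, 1.0, 0.0), (1.1, 1.0, 0.10), (0.9, 1.0, -0.10)])
    def test_signed_values(self, x_hat, x_exp, expected):
        assert relative_error(x_hat, x_exp) == pytest.approx(expected,
                                                             abs=1e-12)

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError):
            relative_error(1.0, 0.0)


class TestCumulative:
    def test_constant_series_constant_cumulative(self):
        s = _series([5.0] * 20, stride=50.0)
        c = cumulative_mean(s, 250.0)
        assert np.all(c.values == 5.0)

    def test_final_point_equals_full_estimator(self):
        rng = np.random.default_rng(4)
        s = _series(rng.normal(size=40), stride=50.0)
        c = cumulative_mean(s, 500.0)
        assert c.values[-1] == pytest.approx(s.mean(), rel=1e-12)
        # also for a fluctuation estimator
        ck = cumulative_series(
            lambda p: isothermal_compressibility(
                ScalarSeries("V", p.times, 1000.0 + p.values), 300.0).value,
            500.0, s)
        full = isothermal_compressibility(
            ScalarSeries("V", s.times, 1000.0 + s.values), 300.0).value
        assert ck.values[-1] == pytest.approx(full, rel=1e-12)

    def test_window_below_stride_rejected(self):
        with pytest.raises(ValueError):
            cumulative_mean(_series([1.0] * 10, stride=50.0), 20.0)

    def test_iid_convergence_rate_is_sqrt_t(self):
        """|cumulative mean − µ| decays with log-log slope −1/2 ± 0.1.

        The root-mean-square error over independent replicas of the series
        tracks the law-of-large-numbers rate; each replica's cumulative mean
        is computed through the same code path as the single-series API.
        """
        rng = np.random.default_rng(11)
        n, reps = 4096, 100
        errs = []
        for _ in range(reps):
            s = _series(rng.normal(0.0, 1.0, n), stride=1.0)
            c = cumulative_mean(s, 4.0)
            errs.append(c.values ** 2)
        rmse = np.sqrt(np.mean(errs, axis=0))
        t = np.arange(1, len(rmse) + 1) * 4.0
        slope = np.polyfit(np.log10(t), np.log10(rmse), 1)[0]
        assert slope == pytest.approx(-0.5, abs=0.1)


class TestRepeats:
    def test_identical_values_zero_std(self):
        ests = [PropertyEstimate(3.3, "rho", "g/cm^3") for _ in range(5)]
        agg = repeat_statistics(ests)
        assert agg.value == 3.3
        assert agg.std_error == 0.0
        assert agg.n_repeats == 5

    def test_hand_arithmetic(self):
        ests = [PropertyEstimate(v, "kappa", "1/atm") for v in (1.0, 2.0, 3.0)]
        agg = repeat_statistics(ests)
        assert agg.value == 2.0
        assert agg.std_error == pytest.approx(1.0)  # sample std

    def test_mixed_kinds_rejected(self):
        with pytest.raises(ValueError, match="mixed"):
            repeat_statistics([PropertyEstimate(1.0, "kappa", "1/atm"),
                               PropertyEstimate(1.0, "rho", "g/cm^3")])
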