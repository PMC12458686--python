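"""End-to-end protocol, cutoff sweep plumbing, bundle and report."""

import filecmp
import json
from pathlib import Path

import numpy as np
import pytest

from liquidprops.engine import EnsembleSpec
from liquidprops.system import lj_fluid, polar_liquid
from liquidprops.thermo import repeat_statistics
from liquidprops.workflow import (ProtocolSpec, build_report, cutoff_sweep,
                                  run_protocol, save_bundle)

TINY_PROTO = dict(equilibration_len=0.5, production_len=2.0, n_restarts=2,
                  restart_discard=0.25, nvt_len=2.0, gas_len=1.0,
                  log_stride=10, traj_stride=40, density=1.3,
                  cumulative_window=0.5, msd_fit=(0.1, 0.5))


@pytest.fixture(scope="module")
def tiny_results():
    system = lj_fluid(32)
    ens = EnsembleSpec(ensemble="NPT", T_target=150.0, thermostat="langevin",
                       friction=5.0, dt=0.5, r_on=4.0, r_off=5.5, seed=0,
                       barostat_interval=10)
    proto = ProtocolSpec(seed=5, **TINY_PROTO)
    return run_protocol(system, ens, proto)


def test_protocol_produces_all_artifacts(tiny_results):
    r = tiny_results
    assert r.initial_run.kappa.value > 0
    assert len(r.restart_runs) == 2
    assert set(r.aggregates) >= {"kappa", "Cp", "alpha", "rho"}
    assert r.rdf_result is not None
    assert r.msd_result is not None and r.msd_result.D is not None
    assert r.config_hash
    for s in r.cumulative.values():
        assert len(s) >= 1


def test_aggregates_match_repeat_statistics(tiny_results):
    r = tiny_results
    ests = [run.kappa for run in r.restart_runs]
    agg = repeat_statistics(ests)
    assert r.aggregates["kappa"].value == agg.value
    assert r.aggregates["kappa"].std_error == agg.std_error


def test_no_restarts_means_no_aggregates():
    system = lj_fluid(32)
    ens = EnsembleSpec(ensemble="NPT", T_target=150.0, thermostat="langevin",
                       friction=5.0, dt=0.5, r_on=4.0, r_off=5.5, seed=0,
                       barostat_interval=10)
    proto = ProtocolSpec(seed=5, **{**TINY_PROTO, "n_restarts": 0,
                                    "nvt_len": 0.0})
    r = run_protocol(system, ens, proto)
    assert r.restart_runs == []
    assert r.aggregates == {}
    assert r.rdf_result is None


def test_protocol_is_deterministic(tiny_results):
    system = lj_fluid(32)
    ens = EnsembleSpec(ensemble="NPT", T_target=150.0, thermostat="langevin",
                       friction=5.0, dt=0.5, r_on=4.0, r_off=5.5, seed=0,
                       barostat_interval=10)
    proto = ProtocolSpec(seed=5, **TINY_PROTO)
    again = run_protocol(system, ens, proto)
    assert again.initial_run.kappa.value == tiny_results.initial_run.kappa.value
    assert again.msd_result.D == tiny_results.msd_result.D
    np.testing.assert_array_equal(again.rdf_result.g,
                                  tiny_results.rdf_result.g)
    assert again.config_hash == tiny_results.config_hash


def test_bundle_and_report_round_trip(tiny_results, tmp_path):
    b1 = tmp_path / "bundle"
    save_bundle(tiny_results, b1)
    assert (b1 / "manifest.json").exists()
    manifest = json.loads((b1 / "manifest.json").read_text())
    assert manifest["config_hash"] == tiny_results.config_hash
    assert "seeds" in manifest and "production" in manifest["seeds"]

    out1 = tmp_path / "report1"
    out2 = tmp_path / "report2"
    w1 = build_report(b1, out1)
    w2 = build_report(b1, out2)
    assert w1 and len(w1) == len(w2)
    for p1, p2 in zip(sorted(out1.iterdir()), sorted(out2.iterdir())):
        assert p1.name == p2.name
        assert filecmp.cmp(p1, p2, shallow=False), f"{p1.name} differs"


def test_report_without_references_has_no_eps_rel(tiny_results, tmp_path):
    b = tmp_path / "bundle"
    save_bundle(tiny_results, b)
    out = tmp_path / "report"
    build_report(b, out)
    table = (out / "properties.txt").read_text()
    assert "eps_rel" not in table


def test_report_with_reference_equal_to_value_is_zero(tiny_results, tmp_path):
    b = tmp_path / "bundle"
    save_bundle(tiny_results, b)
    out = tmp_path / "report"
    kappa_val = tiny_results.initial_run.kappa.value
    build_report(b, out, x_exp={"kappa": kappa_val})
    import pandas as pd
    df = pd.read_csv(out / "properties.csv")
    row = df[(df["property"] == "kappa") & (df["run"] == "initial")]
    assert row["eps_rel"].iloc[0] == pytest.approx(0.0, abs=1e-12)


class TestSweep:
    def test_ladder_validation_before_simulation(self):
        system = polar_liquid(27)
        ens = EnsembleSpec(ensemble="NVT", thermostat="nose_hoover",
                           T_target=300.0, dt=0.5, r_on=3.0, r_off=4.0)
        proto = ProtocolSpec(seed=1, cutoff_ladder=[100.0], **TINY_PROTO)
        with pytest.raises(ValueError, match="box_length/2"):
            cutoff_sweep(system, ens, proto)

    def test_empty_ladder_rejected(self):
        system = polar_liquid(27)
        ens = EnsembleSpec(ensemble="NVT", thermostat="nose_hoover",
                           T_target=300.0, dt=0.5, r_on=3.0, r_off=4.0)
        proto = ProtocolSpec(seed=1, **TINY_PROTO)
        with pytest.raises(ValueError, match="empty"):
            cutoff_sweep(system, ens, proto)

    def test_single_entry_sweep_structure(self):
        """One ladder entry → one row with repeat-based error bars."""
        system = lj_fluid(32)
        ens = EnsembleSpec(ensemble="NVT", T_target=150.0,
                           thermostat="nose_hoover", dt=0.5,
                           r_on=4.0, r_off=5.5, seed=3)
        proto = ProtocolSpec(seed=3, cutoff_ladder=[5.0],
                             **{**TINY_PROTO, "n_restarts": 1})
        rows = cutoff_sweep(system, ens, proto)
        assert len(rows) == 1
        row = rows[0]
        assert row.cutoff == 5.0
        assert row.n_repeats == 2
        assert row.peak_height > 0
        assert np.isfinite(row.D)


def test_ideal_gas_protocol_recovers_compressibility():
    """Full protocol on a non-interacting gas: the repeat-aggregated κ
    matches the closed form 1/P within 3 inter-run standard errors."""
    from liquidprops.frames import Frame
    from liquidprops.system import ideal_gas
    from liquidprops.units import ATM_A3_TO_KJ_PER_MOL, R_KJ_PER_MOL_K

    spec = ideal_gas(100)
    ens = EnsembleSpec(ensemble="NPT", T_target=300.0, P_target=1.0,
                       thermostat="langevin", dt=0.5, barostat_interval=10,
                       r_on=10.0, r_off=12.0, seed=0)
    proto = ProtocolSpec(equilibration_len=5.0, production_len=30.0,
                         n_restarts=5, restart_discard=2.0, nvt_len=0.0,
                         gas_len=0.0, log_stride=10, density=1e-4,
                         cumulative_window=5.0, seed=77)
    V0 = 100 * R_KJ_PER_MOL_K * 300.0 / ATM_A3_TO_KJ_PER_MOL
    rng = np.random.default_rng(77)
    start = Frame(rng.uniform(0.0, V0 ** (1 / 3), (100, 3)), V0 ** (1 / 3))
    r = run_protocol(spec, ens, proto, start=start)
    agg = r.aggregates["kappa"]
    assert agg.n_repeats == 5
    assert abs(agg.value - 1.0) < 3 * agg.std_error / np.sqrt(5)


def test_restart_discard_validation():
    with pytest.raises(ValueError, match="restart_discard"):
        ProtocolSpec(production_len=1.0, restart_discard=2.0)
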