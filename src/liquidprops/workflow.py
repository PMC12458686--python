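"""End-to-end simulation-and-analysis protocol on toy systems.

The protocol mirrors the standard liquid-property workflow: equilibrate
under NPT, run an initial production, restart several independent NPT
productions with freshly drawn velocities (discarding a re-equilibration
span from each), aggregate the fluctuation estimators across the repeats,
and run one NVT leg for structure (RDF) and transport (MSD → D).  A cutoff
sweep repeats the structural/transport leg over a ladder of interaction
cutoffs to expose truncation artifacts: too-short cutoffs over-structure
the liquid and slow diffusion.

All stages are deterministic given the protocol seed; every results bundle
carries the seeds and a config hash.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np

from . import io as lpio
from .engine import (EnsembleSpec, equilibrate, run_gas_phase, run_simulation,
                     with_new_velocities)
from .frames import Frame
from .msd import MsdResult, com_trajectory, diffusion_coefficient, msd, unwrap
from .properties import PropertyEstimate
from .rdf import RdfResult, first_minimum, first_peak, rdf, select_species
from .system import SystemSpec, build_system
from .thermo import (cumulative_series, heat_capacity, heat_of_vaporization,
                     isothermal_compressibility, mean_density,
                     repeat_statistics, thermal_expansion, ThermoInputs)


@dataclass
class ProtocolSpec:
    """Stage lengths (ps), repeat counts and seeds for the full protocol."""

    equilibration_len: float = 5.0
    production_len: float = 50.0
    n_restarts: int = 5
    restart_discard: float = 5.0
    nvt_len: float = 175.0
    gas_len: float = 50.0
    log_stride: int = 100
    traj_stride: int = 100
    seed: int = 0
    density: float = 1.0            # g/cm³ for the builder
    rdf_dr: float = 0.05
    rdf_species: tuple[str, str] | None = None
    msd_fit: tuple[float, float] = (0.1, 0.5)   # fractions of max lag
    cutoff_ladder: list[float] = field(default_factory=list)
    cumulative_window: float = 5.0  # ps

    def __post_init__(self) -> None:
        if self.restart_discard >= self.production_len:
            raise ValueError("restart_discard must be < production_len")
        if self.n_restarts < 0:
            raise ValueError("n_restarts must be >= 0")


@dataclass
class RunProperties:
    """Per-production-run property estimates."""
    kappa: PropertyEstimate
    Cp: PropertyEstimate
    alpha: PropertyEstimate
    rho: PropertyEstimate
    dHvap: PropertyEstimate | None


@dataclass
class ProtocolResults:
    system: SystemSpec
    ensemble: EnsembleSpec
    protocol: ProtocolSpec
    initial_run: RunProperties
    restart_runs: list[RunProperties]
    aggregates: dict[str, PropertyEstimate]
    cumulative: dict[str, object]
    rdf_result: RdfResult | None
    msd_result: MsdResult | None
    series: dict[str, object]
    config_hash: str
    seeds: dict[str, int]


def _hash_config(*objs) -> str:
    blob = json.dumps([_jsonable(o) for o in objs], sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _jsonable(o):
    if hasattr(o, "__dataclass_fields__"):
        return {k: _jsonable(v) for k, v in asdict(o).items()}
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (list, tuple)):
        return [_jsonable(v) for v in o]
    if isinstance(o, dict):
        return {k: _jsonable(v) for k, v in o.items()}
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    return o


def _steps(len_ps: float, dt: float) -> int:
    return max(int(round(len_ps * 1000.0 / dt)), 1)


def _analyze_run(series: dict, system: SystemSpec, ens: EnsembleSpec,
                 e_gas_mean: float | None) -> RunProperties:
    V, H = series["V"], series["H"]
    kappa = isothermal_compressibility(V, ens.T_target)
    cp = heat_capacity(H, system.n_molecules, ens.T_target)
    alpha = thermal_expansion(V, H, ens.T_target)
    rho = mean_density(V, system.total_mass)
    dhvap = None
    if e_gas_mean is not None:
        inputs = ThermoInputs(
            n_molecules=system.n_molecules, T=ens.T_target,
            P_ext=ens.P_target,
            E_liquid=series["E_pot"],
            E_gas=_const_like(series["E_pot"], e_gas_mean))
        dhvap = heat_of_vaporization(inputs)
    return RunProperties(kappa, cp, alpha, rho, dhvap)


def _const_like(s, value):
    from .series import ScalarSeries
    return ScalarSeries("E_gas", s.times, np.full(len(s), value), s.units)


def _discard(series: dict, t_discard_fs: float) -> dict:
    return {k: s.slice_time(s.times[0] + t_discard_fs) for k, s in series.items()}


def run_protocol(system: SystemSpec, ens: EnsembleSpec,
                 proto: ProtocolSpec, start: Frame | None = None,
                 workdir: str | Path | None = None) -> ProtocolResults:
    """Execute equilibration → production → restarts → NVT analysis leg."""
    seeds = {
        "build": proto.seed % (2 ** 31),
        "equil": (proto.seed * 7 + 1) % (2 ** 31),
        "production": (proto.seed * 7 + 2) % (2 ** 31),
        "nvt": (proto.seed * 7 + 3) % (2 ** 31),
        "gas": (proto.seed * 7 + 4) % (2 ** 31),
    }
    for i in range(proto.n_restarts):
        seeds[f"restart{i}"] = (proto.seed * 7 + 10 + i) % (2 ** 31)
    dt = ens.dt

    if start is None:
        start = build_system(system, proto.density, seed=seeds["build"])

    npt = replace(ens, ensemble="NPT", seed=seeds["equil"])
    frame = equilibrate(start, system, npt, _steps(proto.equilibration_len, dt))

    # gas-phase reference for ΔH_vap (single molecule, no PBC)
    e_gas_mean = None
    if system.atoms_per_molecule > 1 or np.any(system.lj_epsilon != 0):
        gas_spec = replace(system, n_molecules=1)
        gas = run_gas_phase(gas_spec, ens.T_target,
                            _steps(proto.gas_len, dt), dt=dt,
                            log_stride=proto.log_stride, seed=seeds["gas"])
        e_gas_mean = gas["E_pot"].mean()
    else:
        gas = None

    prod_steps = _steps(proto.production_len, dt)
    npt_prod = replace(npt, seed=seeds["production"])
    res0 = run_simulation(frame, system, npt_prod, prod_steps,
                          log_stride=proto.log_stride)
    initial = _analyze_run(res0.series, system, ens, e_gas_mean)

    window_fs = proto.cumulative_window * 1000.0
    cumulative = {
        "kappa": cumulative_series(
            lambda v: isothermal_compressibility(v, ens.T_target).value,
            window_fs, res0.series["V"]),
        "Cp": cumulative_series(
            lambda h: heat_capacity(h, system.n_molecules, ens.T_target).value,
            window_fs, res0.series["H"]),
        "alpha": cumulative_series(
            lambda v, h: thermal_expansion(v, h, ens.T_target).value,
            window_fs, res0.series["V"], res0.series["H"]),
        "rho": cumulative_series(
            lambda v: mean_density(v, system.total_mass).value,
            window_fs, res0.series["V"]),
    }

    restarts = []
    discard_fs = proto.restart_discard * 1000.0
    for i in range(proto.n_restarts):
        f_i = with_new_velocities(res0.final_frame, system, ens.T_target,
                                  seeds[f"restart{i}"])
        npt_i = replace(npt, seed=seeds[f"restart{i}"])
        res_i = run_simulation(f_i, system, npt_i, prod_steps,
                               log_stride=proto.log_stride)
        restarts.append(_analyze_run(_discard(res_i.series, discard_fs),
                                     system, ens, e_gas_mean))

    aggregates = {}
    if len(restarts) >= 2:
        for prop in ("kappa", "Cp", "alpha", "rho", "dHvap"):
            ests = [getattr(r, prop) for r in restarts]
            if all(e is not None for e in ests):
                aggregates[prop] = repeat_statistics(ests)

    # NVT leg for structure and transport at the builder density
    rdf_result = msd_result = None
    nvt_series = None
    if proto.nvt_len > 0:
        nvt_frame = build_system(system, proto.density, seed=seeds["build"])
        nvt = replace(ens, ensemble="NVT", thermostat="nose_hoover",
                      seed=seeds["nvt"])
        nvt_frame = equilibrate(nvt_frame, system, nvt,
                                _steps(proto.equilibration_len, dt))
        res_nvt = run_simulation(nvt_frame, system, nvt,
                                 _steps(proto.nvt_len, dt),
                                 log_stride=proto.log_stride,
                                 traj_stride=proto.traj_stride)
        nvt_series = res_nvt.series
        traj = res_nvt.trajectory
        sp = system.atom_species()
        if proto.rdf_species is not None:
            sel_a = select_species(sp, proto.rdf_species[0])
            sel_b = select_species(sp, proto.rdf_species[1])
        else:
            sel_a = sel_b = np.arange(system.n_atoms)
        r_max = min(f.box_length for f in traj) / 2.0
        r_max = np.floor(r_max / proto.rdf_dr) * proto.rdf_dr
        rdf_result = rdf(traj, sel_a, sel_b, proto.rdf_dr, r_max)
        com = com_trajectory(unwrap(traj), system)
        m = msd(com)
        t_max = m.lags[-1]
        msd_result = diffusion_coefficient(
            m, (proto.msd_fit[0] * t_max, proto.msd_fit[1] * t_max))

    results = ProtocolResults(
        system=system, ensemble=ens, protocol=proto,
        initial_run=initial, restart_runs=restarts, aggregates=aggregates,
        cumulative=cumulative, rdf_result=rdf_result, msd_result=msd_result,
        series={"npt": res0.series, "nvt": nvt_series,
                "gas": gas},
        config_hash=_hash_config(system, ens, proto), seeds=seeds)
    if workdir is not None:
        save_bundle(results, workdir)
    return results


@dataclass
class SweepRow:
    cutoff: float
    peak_height: float
    peak_height_std: float
    peak_r: float
    min_depth: float
    D: float
    D_std: float
    n_repeats: int


def cutoff_sweep(system: SystemSpec, ens: EnsembleSpec,
                 proto: ProtocolSpec) -> list[SweepRow]:
    """Repeat the NVT structure/transport leg per cutoff in the ladder.

    Per cutoff: build + equilibrate once, then 1 + n_restarts independent
    NVT productions with fresh velocities; report the RDF first-peak height,
    first-minimum depth and D as mean ± sample std across the repeats.
    """
    if not proto.cutoff_ladder:
        raise ValueError("cutoff_ladder is empty")
    probe = build_system(system, proto.density, seed=proto.seed % (2 ** 31))
    for c in proto.cutoff_ladder:
        if c >= probe.box_length / 2.0:
            raise ValueError(
                f"cutoff {c} Å >= box_length/2 = {probe.box_length / 2:.2f} Å")
    rows = []
    dt = ens.dt
    n_rep = 1 + proto.n_restarts
    for c in proto.cutoff_ladder:
        ens_c = replace(ens, ensemble="NVT", thermostat="nose_hoover",
                        r_off=c, r_on=max(0.5 * c, c - 2.0))
        frame = equilibrate(probe.copy(), system,
                            replace(ens_c, seed=(proto.seed * 13 + 1) % 2**31),
                            _steps(proto.equilibration_len, dt))
        peaks, mins, peak_rs, Ds = [], [], [], []
        for i in range(n_rep):
            seed_i = (proto.seed * 13 + 100 * int(c * 10) + i) % (2 ** 31)
            f_i = with_new_velocities(frame, system, ens.T_target, seed_i)
            res = run_simulation(f_i, system, replace(ens_c, seed=seed_i),
                                 _steps(proto.nvt_len, dt),
                                 log_stride=proto.log_stride,
                                 traj_stride=proto.traj_stride)
            traj = res.trajectory
            sp = system.atom_species()
            if proto.rdf_species is not None:
                sel_a = select_species(sp, proto.rdf_species[0])
                sel_b = select_species(sp, proto.rdf_species[1])
            else:
                sel_a = sel_b = np.arange(system.n_atoms)
            r_max = np.floor(frame.box_length / 2.0 / proto.rdf_dr) * proto.rdf_dr
            g = rdf(traj, sel_a, sel_b, proto.rdf_dr, r_max)
            pr, ph = first_peak(g)
            _, mn = first_minimum(g)
            peaks.append(ph)
            peak_rs.append(pr)
            mins.append(mn)
            com = com_trajectory(unwrap(traj), system)
            m = msd(com)
            t_max = m.lags[-1]
            d = diffusion_coefficient(
                m, (proto.msd_fit[0] * t_max, proto.msd_fit[1] * t_max))
            Ds.append(d.D)
        rows.append(SweepRow(
            cutoff=c,
            peak_height=float(np.mean(peaks)),
            peak_height_std=float(np.std(peaks, ddof=1)) if n_rep > 1 else 0.0,
            peak_r=float(np.mean(peak_rs)),
            min_depth=float(np.mean(mins)),
            D=float(np.mean(Ds)),
            D_std=float(np.std(Ds, ddof=1)) if n_rep > 1 else 0.0,
            n_repeats=n_rep))
    return rows


# ---------------------------------------------------------------------------
# Results bundle I/O and reporting
# ---------------------------------------------------------------------------

def _estimate_row(name: str, e: PropertyEstimate, x_exp=None) -> dict:
    row = {"property": name, "value": e.value, "units": e.units,
           "std_error": e.std_error if e.std_error is not None else "",
           "n_repeats": e.n_repeats}
    if x_exp is not None and name in x_exp:
        from .thermo import relative_error
        row["eps_rel"] = relative_error(e.value, x_exp[name])
    return row


def save_bundle(results: ProtocolResults, workdir: str | Path) -> None:
    """Write the results bundle: CSV series, properties table, manifest."""
    wd = Path(workdir)
    wd.mkdir(parents=True, exist_ok=True)
    for stage in ("npt", "nvt", "gas"):
        series = results.series.get(stage)
        if not series:
            continue
        for name, s in series.items():
            lpio.write_series(wd / f"{stage}_{name}.csv", s)
    for name, s in results.cumulative.items():
        lpio.write_series(wd / f"cumulative_{name}.csv", s)
    if results.rdf_result is not None:
        g = results.rdf_result
        rows = ["r_A,g"]
        rows += [f"{r:.6f},{v:.8f}" for r, v in zip(g.r_centers, g.g)]
        (wd / "rdf.csv").write_text("\n".join(rows) + "\n")
    if results.msd_result is not None:
        m = results.msd_result
        rows = ["lag_fs,msd_A2"]
        rows += [f"{t:.4f},{v:.8f}" for t, v in zip(m.lags, m.msd)]
        (wd / "msd.csv").write_text("\n".join(rows) + "\n")
    _write_properties_csv(wd / "properties.csv", results)
    manifest = {
        "config_hash": results.config_hash,
        "seeds": results.seeds,
        "system": _jsonable(results.system),
        "ensemble": _jsonable(results.ensemble),
        "protocol": _jsonable(results.protocol),
        "float_width": "float64",
    }
    if results.msd_result is not None:
        manifest["D_cm2_s"] = results.msd_result.D
        manifest["msd_fit_window_fs"] = list(results.msd_result.fit_window)
        manifest["msd_fit_r2"] = results.msd_result.fit_r2
        manifest["msd_drift_removed"] = results.msd_result.drift_removed
    (wd / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                 sort_keys=True) + "\n")


def _write_properties_csv(path: Path, results: ProtocolResults,
                          x_exp: dict | None = None) -> None:
    import csv
    rows = []
    for name in ("kappa", "Cp", "alpha", "rho", "dHvap"):
        e = getattr(results.initial_run, name)
        if e is not None:
            rows.append({"run": "initial", **_estimate_row(name, e, x_exp)})
    for name, e in results.aggregates.items():
        rows.append({"run": "aggregate", **_estimate_row(name, e, x_exp)})
    if results.msd_result is not None and results.msd_result.D is not None:
        rows.append({"run": "nvt", "property": "D",
                     "value": results.msd_result.D, "units": "cm^2/s",
                     "std_error": "", "n_repeats": 1})
    fields = ["run", "property", "value", "units", "std_error", "n_repeats"]
    if any("eps_rel" in r for r in rows):
        fields.append("eps_rel")
    with open(path, "w", newline="") as fh:
        w = csv.DictWriter(fh, fieldnames=fields, restval="")
        w.writeheader()
        w.writerows(rows)


def build_report(bundle_dir: str | Path, out_dir: str | Path | None = None,
                 x_exp: dict | None = None) -> list[Path]:
    """Render a human-readable report (table + plots) from a saved bundle.

    Every number in the report is re-read from the bundle files; missing
    series are noted, not fatal.  Returns the paths written.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import pandas as pd

    bd = Path(bundle_dir)
    out = Path(out_dir) if out_dir is not None else bd / "report"
    out.mkdir(parents=True, exist_ok=True)
    written = []
    notes = []

    props_path = bd / "properties.csv"
    if props_path.exists():
        df = pd.read_csv(props_path)
        if x_exp:
            df["eps_rel"] = [
                (row["value"] - x_exp[row["property"]]) / x_exp[row["property"]]
                if row["property"] in x_exp else np.nan
                for _, row in df.iterrows()]
        table = out / "properties.txt"
        table.write_text(df.to_string(index=False) + "\n")
        df.to_csv(out / "properties.csv", index=False)
        written += [table, out / "properties.csv"]
    else:
        notes.append("properties.csv missing")

    cum_files = sorted(bd.glob("cumulative_*.csv"))
    if cum_files:
        fig, axes = plt.subplots(len(cum_files), 1, figsize=(6, 2.2 * len(cum_files)),
                                 sharex=True, squeeze=False)
        for ax, f in zip(axes[:, 0], cum_files):
            s = lpio.read_series(f)
            ax.plot(s.times / 1000.0, s.values, lw=1.2)
            ax.set_ylabel(f.stem.replace("cumulative_", ""))
        axes[-1, 0].set_xlabel("time (ps)")
        fig.tight_layout()
        p = out / "convergence.png"
        fig.savefig(p, dpi=110, metadata={"Software": "liquidprops"})
        plt.close(fig)
        written.append(p)
    else:
        notes.append("no cumulative series")

    for stem, xlab, ylab in (("rdf", "r (Å)", "g(r)"),
                             ("msd", "lag (fs)", "MSD (Å$^2$)")):
        f = bd / f"{stem}.csv"
        if f.exists():
            df = pd.read_csv(f)
            fig, ax = plt.subplots(figsize=(5, 3.2))
            ax.plot(df.iloc[:, 0], df.iloc[:, 1], lw=1.2)
            ax.set_xlabel(xlab)
            ax.set_ylabel(ylab)
            fig.tight_layout()
            p = out / f"{stem}.png"
            fig.savefig(p, dpi=110, metadata={"Software": "liquidprops"})
            plt.close(fig)
            written.append(p)
        else:
            notes.append(f"{stem}.csv missing")

    if notes:
        p = out / "NOTES.txt"
        p.write_text("\n".join(notes) + "\n")
        written.append(p)
    return written
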