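"""Shared fixtures: heavier simulation runs are session-scoped so several
tests (and the acceptance checks) can analyze the same trajectories."""

import numpy as np
import pytest

from liquidprops.engine import EnsembleSpec, run_simulation
from liquidprops.frames import Frame
from liquidprops.system import build_system, ideal_gas, lj_fluid
from liquidprops.units import ATM_A3_TO_KJ_PER_MOL, R_KJ_PER_MOL_K


@pytest.fixture(scope="session")
def lj108_frame():
    """108-particle argon-like LJ liquid at reduced density ~0.84."""
    spec = lj_fluid(108)
    return spec, build_system(spec, 1.4, seed=3)


@pytest.fixture(scope="session")
def langevin_nvt_300(lj108_frame):
    """Long Langevin NVT run of the LJ liquid at the 300 K set point."""
    spec, frame = lj108_frame
    ens = EnsembleSpec(ensemble="NVT", T_target=300.0, thermostat="langevin",
                       friction=1.0, dt=0.5, r_on=7.0, r_off=8.0, seed=42)
    return run_simulation(frame, spec, ens, 220000, log_stride=100)


@pytest.fixture(scope="session")
def langevin_nvt_373(lj108_frame):
    """Same liquid thermostatted at the 373.15 K set point."""
    spec, frame = lj108_frame
    ens = EnsembleSpec(ensemble="NVT", T_target=373.15, thermostat="langevin",
                       friction=1.0, dt=0.5, r_on=7.0, r_off=8.0, seed=42)
    return run_simulation(frame, spec, ens, 220000, log_stride=100)


@pytest.fixture(scope="session")
def ideal_gas_npt():
    """Long NPT run of a 200-particle non-interacting gas at 300 K, 1 atm.

    Logged every 5 steps so the series exceeds 1e5 samples; the first 5 ps
    are discarded as equilibration by the consumers via slice_time.
    """
    spec = ideal_gas(200)
    V0 = 200 * R_KJ_PER_MOL_K * 300.0 / ATM_A3_TO_KJ_PER_MOL
    L0 = V0 ** (1.0 / 3.0)
    rng = np.random.default_rng(1)
    frame = Frame(rng.uniform(0.0, L0, (200, 3)), L0)
    ens = EnsembleSpec(ensemble="NPT", T_target=300.0, P_target=1.0,
                       thermostat="langevin", dt=0.5, barostat_interval=10,
                       r_on=10.0, r_off=12.0, seed=2)
    res = run_simulation(frame, spec, ens, 600000, log_stride=5)
    return spec, ens, res
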