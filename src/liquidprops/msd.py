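"""Mean squared displacement and Einstein-relation self-diffusion.

MSD(t) averages |x⃗_i(s+t) − x⃗_i(s)|² over all particles i and all time
origins s ∈ [0, T − t] (the windowed estimator), computed with the
FFT-based correlation algorithm; the self-diffusion coefficient is
D = slope/6 of a straight-line fit to MSD(t) over a configurable lag
window, converted Å²/fs → cm²/s.

Trajectories must be unwrapped (periodic images made continuous) before
MSD; :func:`unwrap` does this per consecutive-frame minimum image.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .frames import Frame, Trajectory
from .system import SystemSpec
from .units import A2_PER_FS_TO_CM2_PER_S


@dataclass
class MsdResult:
    lags: np.ndarray       # fs
    msd: np.ndarray        # Å²
    n_pairs: np.ndarray    # (time-origin × particle) samples per lag
    fit_window: tuple[float, float] | None = None
    D: float | None = None          # cm²/s
    fit_r2: float | None = None
    drift_removed: bool = False


def unwrap(traj: Trajectory) -> Trajectory:
    """Make each atom's coordinates continuous across periodic boundaries.

    Valid when no atom moves ≥ L/2 between consecutive frames (log densely
    enough for that to hold).
    """
    frames = traj.frames
    out = [frames[0].copy()]
    prev_raw = frames[0].positions
    prev_unwrapped = out[0].positions
    for k in range(1, len(frames)):
        f = frames[k]
        L = f.box_length
        disp = f.positions - prev_raw
        shift = np.round(disp / L)
        disp_mi = disp - L * shift
        if np.any(np.abs(disp_mi) >= L / 2.0):
            raise ValueError(
                f"displacement >= box_length/2 between frames {k-1} and {k}; "
                "log frames more densely")
        new = prev_unwrapped + disp_mi
        out.append(Frame(new, L, f.time,
                         None if f.velocities is None else f.velocities.copy(),
                         list(f.species)))
        prev_raw = f.positions
        prev_unwrapped = new
    return Trajectory(out)


def com_trajectory(traj: Trajectory, spec: SystemSpec) -> Trajectory:
    """Per-molecule mass-weighted center-of-mass trajectory.

    Expects an unwrapped input (images made continuous), otherwise molecular
    centers jump at boundaries.
    """
    if traj.n_atoms != spec.n_atoms:
        raise ValueError(
            f"trajectory has {traj.n_atoms} atoms, spec expects {spec.n_atoms}")
    m = spec.atoms_per_molecule
    w = spec.masses / spec.molecule_mass
    out = []
    for f in traj:
        pos = f.positions.reshape(spec.n_molecules, m, 3)
        com = np.einsum("a,nad->nd", w, pos)
        out.append(Frame(com, f.box_length, f.time,
                         species=["M"] * spec.n_molecules))
    return Trajectory(out)


def _msd_fft_single(x: np.ndarray) -> np.ndarray:
    """All-origin MSD of one (T, 3) track via the FFT correlation identity."""
    T = x.shape[0]
    nfft = 1 << (2 * T - 1).bit_length()
    s2 = np.zeros(T)
    for d in range(x.shape[1]):
        f = np.fft.rfft(x[:, d], nfft)
        s2 += np.fft.irfft(f * np.conj(f), nfft)[:T].real
    sq = np.sum(x * x, axis=1)
    q = 2.0 * sq.sum()
    s1 = np.empty(T)
    for t in range(T):
        if t > 0:
            q -= sq[t - 1] + sq[T - t]
        s1[t] = q / (T - t)
    return s1 - 2.0 * s2 / (T - np.arange(T))


def msd(com: Trajectory, remove_drift: bool = True) -> MsdResult:
    """Windowed MSD over all molecules and all time origins.

    remove_drift subtracts the system center-of-mass position (equal
    weights over the tracked centers) per frame before the analysis, so a
    thermostat-induced net drift does not inflate the apparent diffusion.
    """
    if len(com) < 3:
        raise ValueError("need at least 3 frames")
    times = com.times()
    dt = np.diff(times)
    if np.max(dt) - np.min(dt) > 1e-9 * max(dt[0], 1.0):
        raise ValueError("frames must be uniformly strided")
    X = com.positions()                      # (T, N, 3)
    T, N, _ = X.shape
    if remove_drift and N > 1:
        X = X - X.mean(axis=1, keepdims=True)
    else:
        remove_drift = False
    acc = np.zeros(T)
    for i in range(N):
        acc += _msd_fft_single(np.ascontiguousarray(X[:, i, :]))
    acc[0] = 0.0  # exact by definition; FFT path leaves ~1e-15 roundoff
    lags = times - times[0]
    n_pairs = (T - np.arange(T)) * N
    return MsdResult(lags, acc / N, n_pairs, drift_removed=remove_drift)


def msd_direct(com: Trajectory, remove_drift: bool = True) -> MsdResult:
    """O(T²) double-loop reference implementation (oracle for the FFT path)."""
    X = com.positions()
    T, N, _ = X.shape
    if remove_drift and N > 1:
        X = X - X.mean(axis=1, keepdims=True)
    else:
        remove_drift = False
    times = com.times()
    out = np.zeros(T)
    for t in range(T):
        disp = X[t:] - X[:T - t]
        out[t] = np.mean(np.sum(disp * disp, axis=2))
    return MsdResult(times - times[0], out, (T - np.arange(T)) * N,
                     drift_removed=remove_drift)


def diffusion_coefficient(m: MsdResult,
                          fit_window: tuple[float, float] | None = None
                          ) -> MsdResult:
    """Least-squares D = slope/6 over the lag window (default 10–50% of T).

    Returns a copy of ``m`` with D (cm²/s), the window and the fit r²
    filled in; a low r² flags a fit outside the diffusive regime.
    """
    t_max = float(m.lags[-1])
    if fit_window is None:
        fit_window = (0.1 * t_max, 0.5 * t_max)
    t_lo, t_hi = fit_window
    if not (0 <= t_lo < t_hi <= t_max):
        raise ValueError("fit window must satisfy 0 <= t_lo < t_hi <= max lag")
    mask = (m.lags >= t_lo) & (m.lags <= t_hi)
    if np.count_nonzero(mask) < 10:
        raise ValueError("fit window too narrow: fewer than 10 lags")
    t = m.lags[mask]
    y = m.msd[mask]
    slope, intercept = np.polyfit(t, y, 1)
    pred = slope * t + intercept
    ss_res = float(np.sum((y - pred) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    D = slope / 6.0 * A2_PER_FS_TO_CM2_PER_S
    return MsdResult(m.lags, m.msd, m.n_pairs, (t_lo, t_hi),
                     float(D), float(r2), m.drift_removed)
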