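"""Text-format readers and writers: extended-XYZ trajectories, CSV series.

Only cubic boxes are supported; the lattice record in each frame's comment
line must be diagonal with equal entries.  Observable series are two-column
CSV files whose header names the observable and its units, so fixtures stay
diffable and language-neutral.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Sequence

import numpy as np

from .frames import Frame, Trajectory
from .series import ScalarSeries


class FormatError(ValueError):
    """Malformed trajectory or series file."""


_LATTICE_RE = re.compile(r'Lattice="([^"]+)"')
_KV_RE = re.compile(r'(\w+)=("[^"]*"|\S+)')


def _parse_comment(line: str, frame_index: int) -> tuple[float, float, bool]:
    m = _LATTICE_RE.search(line)
    if m is None:
        raise FormatError(f"frame {frame_index}: missing Lattice record")
    vals = np.array([float(x) for x in m.group(1).split()])
    if vals.size != 9:
        raise FormatError(f"frame {frame_index}: lattice must have 9 entries")
    lat = vals.reshape(3, 3)
    diag = np.diag(lat)
    if np.any(lat - np.diag(diag) != 0.0) or not (diag[0] == diag[1] == diag[2]):
        raise FormatError(f"frame {frame_index}: non-cubic lattice")
    if diag[0] <= 0:
        raise FormatError(f"frame {frame_index}: non-positive box length")
    time = 0.0
    has_vel = False
    for key, raw in _KV_RE.findall(line):
        if key == "Time":
            time = float(raw.strip('"'))
        elif key == "Properties":
            has_vel = "vel" in raw
    return float(diag[0]), time, has_vel


def read_frames(path: str | Path) -> Trajectory:
    """Read an extended-XYZ trajectory (cubic lattice per frame)."""
    lines = Path(path).read_text().splitlines()
    frames: list[Frame] = []
    i = 0
    k = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].strip())
        except ValueError as e:
            raise FormatError(f"frame {k}: bad atom-count header") from e
        if i + 1 + n > len(lines):
            raise FormatError(f"frame {k}: truncated (expected {n} atoms)")
        box, time, has_vel = _parse_comment(lines[i + 1], k)
        species, pos, vel = [], [], []
        for j in range(n):
            parts = lines[i + 2 + j].split()
            want = 7 if has_vel else 4
            if len(parts) < want:
                raise FormatError(f"frame {k}: atom line {j} has "
                                  f"{len(parts)} fields, expected {want}")
            species.append(parts[0])
            pos.append([float(x) for x in parts[1:4]])
            if has_vel:
                vel.append([float(x) for x in parts[4:7]])
        # guard against the next header being an atom line (atom-count drift)
        frames.append(Frame(np.array(pos), box, time,
                            np.array(vel) if has_vel else None, species))
        i += 2 + n
        k += 1
    if not frames:
        raise FormatError("no frames found")
    n0 = frames[0].n_atoms
    for k, f in enumerate(frames):
        if f.n_atoms != n0:
            raise FormatError(f"frame {k}: atom count {f.n_atoms} != {n0}")
    return Trajectory(frames)


def write_frames(path: str | Path, traj: Trajectory | Sequence[Frame]) -> None:
    """Write frames as extended-XYZ with a cubic Lattice record."""
    frames = traj.frames if isinstance(traj, Trajectory) else list(traj)
    out = []
    for f in frames:
        L = f.box_length
        props = "species:S:1:pos:R:3"
        if f.velocities is not None:
            props += ":vel:R:3"
        out.append(str(f.n_atoms))
        out.append(f'Lattice="{L:.10f} 0.0 0.0 0.0 {L:.10f} 0.0 0.0 0.0 '
                   f'{L:.10f}" Properties={props} Time={f.time:.6f}')
        for j in range(f.n_atoms):
            row = f"{f.species[j]} " + " ".join(
                f"{x:.8f}" for x in f.positions[j])
            if f.velocities is not None:
                row += " " + " ".join(f"{v:.10f}" for v in f.velocities[j])
            out.append(row)
    Path(path).write_text("\n".join(out) + "\n")


def read_series(path: str | Path) -> ScalarSeries:
    """Read a (time_fs, value) CSV written by :func:`write_series`."""
    lines = [ln for ln in Path(path).read_text().splitlines() if ln.strip()]
    if not lines:
        raise FormatError("empty series file")
    header = [h.strip() for h in lines[0].split(",")]
    if len(header) != 2 or header[0] != "time_fs":
        raise FormatError("series header must be 'time_fs,<name>[ (units)]'")
    m = re.match(r"(.+?)\s*\(([^)]*)\)\s*$", header[1])
    name, units = (m.group(1), m.group(2)) if m else (header[1], "")
    data = np.array([[float(x) for x in ln.split(",")] for ln in lines[1:]])
    if data.size == 0:
        raise FormatError("series file has no data rows")
    return ScalarSeries(name, data[:, 0], data[:, 1], units)


def write_series(path: str | Path, s: ScalarSeries) -> None:
    label = f"{s.name} ({s.units})" if s.units else s.name
    rows = [f"time_fs,{label}"]
    rows += [f"{t:.6f},{v:.12g}" for t, v in zip(s.times, s.values)]
    Path(path).write_text("\n".join(rows) + "\n")
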