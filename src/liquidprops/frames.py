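"""Snapshot and trajectory containers for periodic cubic systems."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np


@dataclass
class Frame:
    """One snapshot of a periodic cubic system.

    positions : (N, 3) float array, Å
    velocities : (N, 3) float array, Å/fs, or None
    box_length : float, Å (cubic box, V = L³)
    time : float, fs
    species : length-N list of element labels (optional, defaults to "X")
    """

    positions: np.ndarray
    box_length: float
    time: float = 0.0
    velocities: np.ndarray | None = None
    species: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("positions must be an (N, 3) array")
        if self.box_length <= 0:
            raise ValueError("box_length must be positive")
        if self.velocities is not None:
            self.velocities = np.asarray(self.velocities, dtype=float)
            if self.velocities.shape != self.positions.shape:
                raise ValueError("velocities must match positions in shape")
        if not self.species:
            self.species = ["X"] * self.n_atoms
        elif len(self.species) != self.n_atoms:
            raise ValueError("species must have one label per atom")

    @property
    def n_atoms(self) -> int:
        return self.positions.shape[0]

    @property
    def volume(self) -> float:
        return float(self.box_length) ** 3

    def wrapped(self) -> "Frame":
        """Copy with positions wrapped into [0, L) per coordinate."""
        pos = np.mod(self.positions, self.box_length)
        # mod can return L for tiny negative inputs after rounding
        pos[pos >= self.box_length] -= self.box_length
        return Frame(pos, self.box_length, self.time,
                     None if self.velocities is None else self.velocities.copy(),
                     list(self.species))

    def copy(self) -> "Frame":
        return Frame(self.positions.copy(), self.box_length, self.time,
                     None if self.velocities is None else self.velocities.copy(),
                     list(self.species))


class Trajectory:
    """An ordered sequence of :class:`Frame` with a constant atom count."""

    def __init__(self, frames: Sequence[Frame]):
        frames = list(frames)
        if not frames:
            raise ValueError("trajectory must contain at least one frame")
        n = frames[0].n_atoms
        for i, f in enumerate(frames):
            if f.n_atoms != n:
                raise ValueError(
                    f"frame {i} has {f.n_atoms} atoms, expected {n}")
        self.frames = frames

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self) -> Iterator[Frame]:
        return iter(self.frames)

    def __getitem__(self, i):
        if isinstance(i, slice):
            return Trajectory(self.frames[i])
        return self.frames[i]

    @property
    def n_atoms(self) -> int:
        return self.frames[0].n_atoms

    def times(self) -> np.ndarray:
        return np.array([f.time for f in self.frames])

    def positions(self) -> np.ndarray:
        """(n_frames, N, 3) stacked positions."""
        return np.stack([f.positions for f in self.frames])


def minimum_image(dr: np.ndarray, box_length: float) -> np.ndarray:
    """Minimum-image displacement(s) for a cubic box."""
    return dr - box_length * np.round(dr / box_length)
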