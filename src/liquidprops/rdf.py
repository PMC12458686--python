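"""Radial distribution functions under cubic periodic boundaries.

Each frame's minimum-image pair distances between two atom selections are
histogrammed into half-open bins [r, r+dr) and normalized by the frame's
instantaneous number density and the exact shell volume
(4/3)π[(r+dr)³ − r³]; g(r) is the average of the per-frame normalized
histograms, so NPT volume fluctuations are handled per frame.  Self-pairs
are excluded when the selections overlap; identical selections count each
unordered pair once.

Neighbor search uses a periodic k-d tree (scipy cKDTree, boxsize); the tests
hold it exactly equal to a naive O(N²) double loop.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .frames import Trajectory


@dataclass
class RdfResult:
    bin_edges: np.ndarray    # Å, len n_bins + 1
    g: np.ndarray            # dimensionless, per bin
    rho_ref: float           # number density (of selection b) used downstream
    n_frames: int
    counts: np.ndarray       # raw pair counts per bin, summed over frames

    @property
    def r_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def dr(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])

    def shell_volumes(self) -> np.ndarray:
        lo = self.bin_edges[:-1]
        hi = self.bin_edges[1:]
        return 4.0 / 3.0 * np.pi * (hi ** 3 - lo ** 3)


def _pair_distances_kdtree(pos_a, pos_b, box, r_max, same_selection):
    """Minimum-image distances < r_max (and < box/2) via periodic k-d tree."""
    wrap = lambda p: np.mod(p, box)
    limit = min(r_max, box / 2.0)
    if same_selection:
        tree = cKDTree(wrap(pos_a), boxsize=box)
        pairs = tree.query_pairs(limit, output_type="ndarray")
        if len(pairs) == 0:
            return np.empty(0)
        d = _min_image_dist(pos_a[pairs[:, 0]], pos_a[pairs[:, 1]], box)
    else:
        tree_a = cKDTree(wrap(pos_a), boxsize=box)
        tree_b = cKDTree(wrap(pos_b), boxsize=box)
        pairs = tree_a.query_ball_tree(tree_b, limit)
        ii = np.concatenate([[i] * len(js) for i, js in enumerate(pairs)]) \
            if any(pairs) else np.empty(0, int)
        jj = np.concatenate([js for js in pairs if js]).astype(int) \
            if any(pairs) else np.empty(0, int)
        if len(ii) == 0:
            return np.empty(0)
        d = _min_image_dist(pos_a[ii], pos_b[jj], box)
    # strict inequalities: drop d == limit (half-open bins; L/2 ambiguous)
    return d[d < limit]


def _min_image_dist(p, q, box):
    dr = p - q
    dr -= box * np.round(dr / box)
    return np.linalg.norm(dr, axis=1)


def rdf(traj: Trajectory, sel_a, sel_b, dr: float, r_max: float,
        normalize_by: str = "instantaneous") -> RdfResult:
    """RDF between atom index selections ``sel_a`` and ``sel_b``.

    normalize_by: "instantaneous" (per-frame density, the NPT-correct
    choice) or "mean" (trajectory-mean density, for comparison).
    """
    sel_a = np.asarray(sel_a, dtype=int)
    sel_b = np.asarray(sel_b, dtype=int)
    if len(sel_a) == 0 or len(sel_b) == 0:
        raise ValueError("empty atom selection")
    if dr <= 0:
        raise ValueError("dr must be positive")
    if normalize_by not in ("instantaneous", "mean"):
        raise ValueError("normalize_by must be 'instantaneous' or 'mean'")
    n_bins = int(round(r_max / dr))
    if abs(n_bins * dr - r_max) > 1e-9 * max(r_max, 1.0):
        n_bins = int(np.floor(r_max / dr + 1e-12))
    edges = np.arange(n_bins + 1) * dr
    r_max = edges[-1]
    shell = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)

    same = (len(sel_a) == len(sel_b)) and np.array_equal(
        np.sort(sel_a), np.sort(sel_b))
    overlap = np.intersect1d(sel_a, sel_b)
    if len(overlap) and not same:
        raise ValueError("selections must be identical or disjoint")

    counts_total = np.zeros(n_bins)
    g_acc = np.zeros(n_bins)
    vols = []
    for f in traj:
        if r_max > f.box_length / 2.0 + 1e-12:
            raise ValueError(
                f"r_max = {r_max} Å exceeds box_length/2 = "
                f"{f.box_length / 2.0:.3f} Å")
        d = _pair_distances_kdtree(f.positions[sel_a], f.positions[sel_b],
                                   f.box_length, r_max, same)
        idx = np.floor(d / dr).astype(int)
        idx = idx[idx < n_bins]
        counts = np.bincount(idx, minlength=n_bins).astype(float)
        counts_total += counts
        V = f.volume
        vols.append(V)
        if same:
            n = len(sel_a)
            pair_density = n * (n - 1) / 2.0 / V
        else:
            pair_density = len(sel_a) * len(sel_b) / V
        if normalize_by == "instantaneous":
            g_acc += counts / (pair_density * shell)
    n_frames = len(traj)
    if normalize_by == "instantaneous":
        g = g_acc / n_frames
    else:
        v_mean = float(np.mean(vols))
        if same:
            n = len(sel_a)
            pair_density = n * (n - 1) / 2.0 / v_mean
        else:
            pair_density = len(sel_a) * len(sel_b) / v_mean
        g = counts_total / n_frames / (pair_density * shell)

    v_mean = float(np.mean(vols))
    n_b_eff = len(sel_b) - 1 if same else len(sel_b)
    rho_ref = max(n_b_eff, 1) / v_mean
    return RdfResult(edges, g, rho_ref, n_frames, counts_total)


def coordination_number(result: RdfResult, r_cut: float) -> float:
    """n(r_cut) = ρ_ref Σ_{bins ≤ r_cut} g·V_shell (bins fully inside r_cut)."""
    edges = result.bin_edges
    if not (edges[0] <= r_cut <= edges[-1] + 1e-12):
        raise ValueError(f"r_cut = {r_cut} outside binned range "
                         f"[{edges[0]}, {edges[-1]}]")
    shell = result.shell_volumes()
    inside = edges[1:] <= r_cut + 1e-12
    return float(result.rho_ref * np.sum(result.g[inside] * shell[inside]))


def first_peak(result: RdfResult) -> tuple[float, float]:
    """(r, g) of the global maximum of g(r)."""
    i = int(np.argmax(result.g))
    return float(result.r_centers[i]), float(result.g[i])


def first_minimum(result: RdfResult) -> tuple[float, float]:
    """(r, g) of the first local minimum after the first peak."""
    g = result.g
    i0 = int(np.argmax(g))
    for i in range(i0 + 1, len(g) - 1):
        if g[i] <= g[i - 1] and g[i] <= g[i + 1]:
            return float(result.r_centers[i]), float(g[i])
    i = i0 + int(np.argmin(g[i0:]))
    return float(result.r_centers[i]), float(g[i])


def select_species(species: list[str], label: str) -> np.ndarray:
    """Atom indices whose element label equals ``label``."""
    idx = np.array([i for i, s in enumerate(species) if s == label], dtype=int)
    if len(idx) == 0:
        raise ValueError(f"no atoms with species {label!r}")
    return idx
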