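"""Unwrapping, center-of-mass reduction, MSD and diffusion fits."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from liquidprops.frames import Frame, Trajectory
from liquidprops.msd import (com_trajectory, diffusion_coefficient, msd,
                             msd_direct, unwrap)
from liquidprops.system import Bond, SystemSpec


def _traj_from_positions(pos, box, dt=10.0):
    """pos: (T, N, 3) array → Trajectory."""
    return Trajectory([Frame(pos[t], box, t * dt) for t in range(len(pos))])


class TestUnwrap:
    def test_single_boundary_crossing_monotone(self):
        x = np.array([[8.0], [9.0], [0.2], [1.2]])  # crosses +x at box 10
        pos = np.zeros((4, 1, 3))
        pos[:, 0, 0] = x[:, 0]
        traj = _traj_from_positions(pos, 10.0)
        un = unwrap(traj)
        xs = [f.positions[0, 0] for f in un]
        assert np.all(np.diff(xs) > 0)
        assert xs[-1] == pytest.approx(11.2)

    def test_stationary_identity(self):
        pos = np.tile(np.array([[1.0, 2.0, 3.0]]), (5, 1, 1))
        traj = _traj_from_positions(pos, 10.0)
        un = unwrap(traj)
        for f0, f1 in zip(traj, un):
            np.testing.assert_array_equal(f0.positions, f1.positions)

    @settings(derandomize=True, max_examples=20)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_wrap_unwrap_round_trip(self, seed):
        """Random walks wrapped into the box unwrap to the ground truth."""
        rng = np.random.default_rng(seed)
        truth = np.cumsum(rng.normal(0, 1.5, (40, 6, 3)), axis=0)
        box = 20.0  # keeps every per-frame jump safely below box/2
        wrapped = np.mod(truth, box)
        un = unwrap(_traj_from_positions(wrapped, box))
        # unwrapped differs from truth only by each atom's initial image
        shift = truth[0] - un[0].positions
        for t in range(40):
            np.testing.assert_allclose(un[t].positions + shift, truth[t],
                                       atol=1e-9)

    def test_too_large_jump_rejected(self):
        pos = np.zeros((2, 1, 3))
        pos[1, 0, 0] = 5.0  # exactly box/2
        with pytest.raises(ValueError, match="densely"):
            unwrap(_traj_from_positions(pos, 10.0))


class TestCom:
    SPEC = SystemSpec(2, 2, [1.0, 3.0], [3.0, 3.0], [0.1, 0.1],
                      bonds=[Bond(0, 1, 100.0, 1.0)], name="ab")

    def test_homonuclear_midpoint(self):
        spec = SystemSpec(1, 2, [2.0, 2.0], [3.0, 3.0], [0.1, 0.1],
                          bonds=[Bond(0, 1, 100.0, 2.0)])
        pos = np.array([[[0.0, 0, 0], [2.0, 0, 0]]])
        com = com_trajectory(_traj_from_positions(pos, 50.0), spec)
        np.testing.assert_allclose(com[0].positions, [[1.0, 0, 0]])

    def test_mass_weighted_mean(self):
        pos = np.array([[[0.0, 0, 0], [4.0, 0, 0],
                         [10.0, 0, 0], [14.0, 0, 0]]])
        com = com_trajectory(_traj_from_positions(pos, 50.0), self.SPEC)
        # masses (1, 3): com at 3/4 along the bond
        np.testing.assert_allclose(com[0].positions[:, 0], [3.0, 13.0])

    def test_single_atom_molecules_identity(self):
        spec = SystemSpec(3, 1, [1.0], [3.0], [0.1])
        pos = np.random.default_rng(0).normal(size=(4, 3, 3))
        traj = _traj_from_positions(pos, 50.0)
        com = com_trajectory(traj, spec)
        for f0, f1 in zip(traj, com):
            np.testing.assert_allclose(f1.positions, f0.positions)

    def test_atom_count_mismatch_rejected(self):
        pos = np.zeros((3, 5, 3))
        with pytest.raises(ValueError, match="atoms"):
            com_trajectory(_traj_from_positions(pos, 50.0), self.SPEC)


class TestMsd:
    def test_stationary_is_zero(self):
        pos = np.tile(np.random.default_rng(1).normal(size=(1, 8, 3)),
                      (20, 1, 1))
        m = msd(_traj_from_positions(pos, 50.0))
        np.testing.assert_allclose(m.msd, 0.0, atol=1e-12)

    def test_ballistic_closed_form(self):
        """Constant velocity v: MSD(t) = v²t² exactly, all origins equal."""
        v = 0.03
        t = np.arange(30) * 10.0
        pos = np.zeros((30, 1, 3))
        pos[:, 0, 0] = v * t
        m = msd(_traj_from_positions(pos, 10.0), remove_drift=False)
        assert m.msd[0] == 0.0
        np.testing.assert_allclose(m.msd[1:], (v * m.lags[1:]) ** 2,
                                   rtol=1e-10)

    def test_fft_equals_direct_double_loop(self):
        """50-frame random-walk fixture: fast path ≡ O(T²) oracle."""
        rng = np.random.default_rng(0)
        pos = np.cumsum(rng.normal(size=(50, 5, 3)), axis=0)
        traj = _traj_from_positions(pos, 10.0)
        m_fast = msd(traj, remove_drift=False)
        m_slow = msd_direct(traj, remove_drift=False)
        np.testing.assert_allclose(m_fast.msd[1:], m_slow.msd[1:],
                                   rtol=1e-9)
        assert m_fast.msd[0] == pytest.approx(0.0, abs=1e-9)
        np.testing.assert_array_equal(m_fast.n_pairs, m_slow.n_pairs)

    def test_n_pairs_decreasing(self):
        rng = np.random.default_rng(2)
        pos = np.cumsum(rng.normal(size=(20, 3, 3)), axis=0)
        m = msd(_traj_from_positions(pos, 10.0))
        assert np.all(np.diff(m.n_pairs) < 0)

    def test_nonuniform_stride_rejected(self):
        frames = [Frame(np.zeros((2, 3)), 10.0, t)
                  for t in (0.0, 10.0, 30.0)]
        with pytest.raises(ValueError, match="strided"):
            msd(Trajectory(frames))


class TestDiffusion:
    def test_exact_linear_input(self):
        """MSD(t) = 6 D₀ t recovers D₀ = 2.3e-5 cm²/s to 1e-10 relative."""
        D0 = 2.3e-5  # cm²/s
        lags = np.arange(100) * 100.0
        m = msd(_traj_from_positions(np.zeros((3, 1, 3)), 10.0))
        from liquidprops.msd import MsdResult
        syn = MsdResult(lags, 6.0 * (D0 / 0.1) * lags,
                        (100 - np.arange(100)) * 1)
        res = diffusion_coefficient(syn, (1000.0, 8000.0))
        assert res.D == pytest.approx(D0, rel=1e-10)
        assert res.fit_r2 == pytest.approx(1.0, abs=1e-12)

    def test_ballistic_regime_flagged_by_low_r2(self):
        from liquidprops.msd import MsdResult
        lags = np.arange(200) * 10.0
        syn = MsdResult(lags, (0.03 * lags) ** 2, 200 - np.arange(200))
        res = diffusion_coefficient(syn, (200.0, 1500.0))
        assert res.fit_r2 < 0.99

    def test_window_too_narrow_rejected(self):
        from liquidprops.msd import MsdResult
        lags = np.arange(100) * 10.0
        syn = MsdResult(lags, lags.copy(), 100 - np.arange(100))
        with pytest.raises(ValueError, match="narrow"):
            diffusion_coefficient(syn, (0.0, 50.0))

    def test_translation_and_relabeling_invariance(self):
        rng = np.random.default_rng(8)
        pos = np.cumsum(rng.normal(size=(60, 4, 3)), axis=0)
        base = diffusion_coefficient(
            msd(_traj_from_positions(pos, 10.0)), (100.0, 300.0)).D
        shifted = diffusion_coefficient(
            msd(_traj_from_positions(pos + 123.4, 10.0)), (100.0, 300.0)).D
        perm = pos[:, [2, 0, 3, 1], :]
        relabeled = diffusion_coefficient(
            msd(_traj_from_positions(perm, 10.0)), (100.0, 300.0)).D
        assert shifted == pytest.approx(base, rel=1e-9)
        assert relabeled == pytest.approx(base, rel=1e-9)
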