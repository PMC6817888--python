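"""DPD pair, bond and angle forces; neighbor search; noise statistics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import dpdshear as dpd
from dpdshear import _kernels
from dpdshear.forcefield import InteractionTable

from conftest import brute_force_pair_forces, numpy_pair_noise, two_bead_state


class TestWeight:
    @pytest.mark.parametrize("r,rc,expected", [
        (0.0, 1.0, 1.0),
        (1.0, 1.0, 0.0),     # open interval: zero at the cutoff
        (0.3, 1.0, 0.7),
        (2.0, 1.0, 0.0),
    ])
    def test_values(self, r, rc, expected):
        assert dpd.weight(r, rc) == pytest.approx(expected, abs=1e-15)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            dpd.weight(-0.1)


class TestPairForces:
    def test_beyond_cutoff_no_contribution(self):
        st_ = two_bead_state(1.2)
        f, e = dpd.pair_forces(st_, InteractionTable())
        assert np.all(f == 0) and e == 0

    def test_conservative_magnitude_at_half_cutoff(self):
        st_ = two_bead_state(0.5)
        table = InteractionTable(sigma=0.0, gamma=0.0)
        f, e = dpd.pair_forces(st_, table)
        # a w(r) = 50 * 0.5 = 25 along the line of centers, equal and opposite
        assert f[0] == pytest.approx([-25.0, 0, 0], abs=1e-12)
        assert np.allclose(f[0], -f[1])
        assert e == pytest.approx(0.5 * 50 * 0.5 ** 2, abs=1e-12)

    def test_equal_velocities_kill_dissipative_channel(self):
        # identical velocities give v_ij = 0: forces must match the
        # zero-velocity evaluation exactly (same noise seed)
        v = [[0.7, -0.2, 0.3]] * 2
        table = InteractionTable()
        f_moving, _ = dpd.pair_forces(two_bead_state(0.5, velocities=v),
                                      table, seed=3)
        f_rest, _ = dpd.pair_forces(two_bead_state(0.5), table, seed=3)
        assert np.array_equal(f_moving, f_rest)

    def test_newtons_third_law_all_channels(self, small_water):
        f, _ = dpd.pair_forces(small_water, InteractionTable(), dt=0.01, seed=9)
        assert np.abs(f.sum(axis=0)).max() <= 1e-9

    def test_noise_seed_determinism(self, small_water):
        f1, _ = dpd.pair_forces(small_water, InteractionTable(), seed=5)
        f2, _ = dpd.pair_forces(small_water, InteractionTable(), seed=5)
        f3, _ = dpd.pair_forces(small_water, InteractionTable(), seed=6)
        assert np.array_equal(f1, f2)
        assert not np.array_equal(f1, f3)


class TestBondForces:
    def make(self, r):
        return two_bead_state(r), np.array([[0, 1]])

    def test_equilibrium_length_zero_force(self):
        st_, bonds = self.make(0.7)
        f, e = dpd.bond_forces(st_, bonds, 100.0, 0.7)
        assert np.abs(f).max() < 1e-12 and e < 1e-24

    def test_compressed_bond_repels(self):
        st_, bonds = self.make(0.35)
        f, e = dpd.bond_forces(st_, bonds, 100.0, 0.7)
        # 100 (1 - 0.5) = 50 pushing bead 0 outward (to smaller x)
        assert f[0, 0] == pytest.approx(-50.0, abs=1e-12)
        assert e == pytest.approx(0.5 * 100 * 0.7 * 0.25, abs=1e-12)

    def test_stretched_bond_attracts(self):
        st_, bonds = self.make(1.4)
        f, _ = dpd.bond_forces(st_, bonds, 100.0, 0.7)
        # 100 (1 - 2) = -100: bead 0 pulled toward bead 1 (larger x)
        assert f[0, 0] == pytest.approx(100.0, abs=1e-12)


class TestAngleForces:
    def bent_state(self, theta):
        pos = np.array([[1.0, 0.0, 0.0],
                        [0.0, 0.0, 0.0],
                        [np.cos(theta), np.sin(theta), 0.0]]) + 2.5
        return dpd.SystemState(positions=pos, velocities=np.zeros((3, 3)),
                               species=np.zeros(3, np.int8), box=np.full(3, 5.0))

    def test_zero_force_at_equilibrium(self):
        st_ = self.bent_state(2 * np.pi / 3)
        f, e = dpd.angle_forces(st_, [[0, 1, 2]], [2 * np.pi / 3], 6.0)
        assert np.abs(f).max() < 1e-9 and e < 1e-18

    def test_energy_of_small_deflection(self):
        th0 = 2 * np.pi / 3
        st_ = self.bent_state(th0 + 0.1)
        _, e = dpd.angle_forces(st_, [[0, 1, 2]], [th0], 6.0)
        assert e == pytest.approx(6.0 * 0.01, rel=1e-10)

    def test_net_force_and_torque_vanish(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            pos = 2.5 + rng.normal(scale=0.5, size=(3, 3))
            st_ = dpd.SystemState(positions=np.mod(pos, 5.0),
                                  velocities=np.zeros((3, 3)),
                                  species=np.zeros(3, np.int8),
                                  box=np.full(3, 5.0))
            f, _ = dpd.angle_forces(st_, [[0, 1, 2]], [np.pi], 6.0)
            assert np.abs(f.sum(axis=0)).max() < 1e-12
            # net torque about the middle bead
            arms = pos - pos[1]
            torque = np.cross(arms, f).sum(axis=0)
            assert np.abs(torque).max() < 1e-10

    def test_force_is_negative_gradient(self):
        rng = np.random.default_rng(8)
        pos = 2.5 + rng.normal(scale=0.4, size=(3, 3))
        theta0, k = [1.9], 6.0
        h = 1e-6

        def energy(p):
            s = dpd.SystemState(positions=p.copy(), velocities=np.zeros((3, 3)),
                                species=np.zeros(3, np.int8), box=np.full(3, 5.0))
            return dpd.angle_forces(s, [[0, 1, 2]], theta0, k)[1]

        st_ = dpd.SystemState(positions=pos.copy(), velocities=np.zeros((3, 3)),
                              species=np.zeros(3, np.int8), box=np.full(3, 5.0))
        f, _ = dpd.angle_forces(st_, [[0, 1, 2]], theta0, k)
        for b in range(3):
            for ax in range(3):
                dp = pos.copy()
                dp[b, ax] += h
                dm = pos.copy()
                dm[b, ax] -= h
                num = -(energy(dp) - energy(dm)) / (2 * h)
                assert f[b, ax] == pytest.approx(num, abs=5e-5)

    def test_zero_length_arm_rejected(self):
        pos = np.array([[2.5, 2.5, 2.5], [2.5, 2.5, 2.5], [3.0, 2.5, 2.5]])
        st_ = dpd.SystemState(positions=pos, velocities=np.zeros((3, 3)),
                              species=np.zeros(3, np.int8), box=np.full(3, 5.0))
        with pytest.raises(ValueError, match="zero-length"):
            dpd.angle_forces(st_, [[0, 1, 2]], [np.pi], 6.0)


class TestNeighborSearch:
    def test_pair_across_periodic_face_reported_once(self):
        pos = np.array([[0.2, 2.0, 2.0], [4.7, 2.0, 2.0]])  # 0.5 apart via wrap
        i, j = dpd.neighbor_pairs(pos, [5.0, 5.0, 5.0], 1.0)
        assert len(i) == 1 and (i[0], j[0]) == (0, 1)

    def test_empty_system(self):
        i, j = dpd.neighbor_pairs(np.empty((0, 3)), [5.0] * 3, 1.0)
        assert len(i) == 0

    def test_small_box_warns_and_falls_back(self):
        pos = np.array([[0.1, 0.1, 0.1], [1.0, 0.1, 0.1]])
        with pytest.warns(UserWarning, match="brute-force"):
            i, j = dpd.neighbor_pairs(pos, [2.0] * 3, 1.0)
        assert len(i) == 1

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(seed=st.integers(0, 10 ** 6))
    def test_cell_list_equals_brute_force_pair_set(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(2, 500)
        L = float(rng.uniform(3.2, 8.0))
        pos = rng.uniform(0, L, size=(n, 3))
        box = np.full(3, L)
        ci, cj = dpd.neighbor_pairs(pos, box, 1.0)
        bi, bj = dpd.neighbor_pairs(pos, box, 1.0, force_brute=True)
        cell = {tuple(sorted(p)) for p in zip(ci.tolist(), cj.tolist())}
        brute = {tuple(sorted(p)) for p in zip(bi.tolist(), bj.tolist())}
        assert cell == brute


class TestPairNoise:
    def test_symmetric_and_deterministic(self):
        assert _kernels.pair_noise(3, 17, 99) == _kernels.pair_noise(17, 3, 99)
        assert _kernels.pair_noise(3, 17, 99) != _kernels.pair_noise(3, 17, 100)

    def test_matches_numpy_reimplementation(self):
        rng = np.random.default_rng(0)
        ii = rng.integers(0, 10 ** 5, size=200)
        jj = rng.integers(0, 10 ** 5, size=200)
        ref = numpy_pair_noise(ii, jj, 1234)
        got = np.array([_kernels.pair_noise(int(a), int(b), 1234)
                        for a, b in zip(ii, jj)])
        # libm vs LLVM transcendentals may differ in the last ulp
        assert np.allclose(got, ref, atol=1e-13, rtol=0)

    def test_gaussian_moments(self):
        ii = np.arange(100_000)
        z = numpy_pair_noise(ii, ii + 1, 7)
        assert abs(z.mean()) < 0.02
        assert abs(z.var() - 1.0) < 0.02


class TestEnergyBookkeeping:
    def test_two_bead_analytic_energies(self):
        r = 0.4
        st_ = two_bead_state(r)
        table = InteractionTable(sigma=0.0, gamma=0.0)
        _, e_pair = dpd.pair_forces(st_, table)
        assert e_pair == pytest.approx(0.5 * 50 * (1 - r) ** 2, abs=1e-12)
        _, e_bond = dpd.bond_forces(st_, [[0, 1]], 100.0, 0.7)
        assert e_bond == pytest.approx(0.5 * 100 * 0.7 * (1 - r / 0.7) ** 2, abs=1e-12)

    def test_cell_path_matches_brute_reference(self, small_water):
        table = InteractionTable()
        f, e = dpd.pair_forces(small_water, table, dt=0.01, seed=77)
        f_ref, e_ref = brute_force_pair_forces(small_water, table, 0.01, 77)
        assert np.abs(f - f_ref).max() < 1e-10
        assert e == pytest.approx(e_ref, abs=1e-9)
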