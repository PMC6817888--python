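"""Gyration tensor, shape factor, flow velocity, energy traces, clustering."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

import dpdshear as dpd
from dpdshear.observables import detect_plateau, mean_flow_velocity_frame


def chain(positions):
    return np.asarray(positions, dtype=float)[None, :, :]


class TestGyrationTensor:
    def test_single_bead_zero_tensor(self):
        g = dpd.gyration_tensor(chain([[1.0, 2.0, 3.0]]))
        assert np.all(g.tensors == 0) and g.rg[0] == 0

    def test_empty_chain_rejected(self):
        with pytest.raises(ValueError):
            dpd.gyration_tensor(np.empty((1, 0, 3)))

    def test_dumbbell(self):
        d = 1.5
        g = dpd.gyration_tensor(chain([[-d / 2, 0, 0], [d / 2, 0, 0]]))
        expected = np.zeros((3, 3))
        expected[0, 0] = d ** 2 / 4
        assert np.allclose(g.tensors[0], expected, atol=1e-15)
        assert g.rg[0] == pytest.approx(d / 2, abs=1e-15)

    @settings(derandomize=True, max_examples=20, deadline=None)
    @given(seed=st.integers(0, 10 ** 6))
    def test_trace_identity(self, seed):
        rng = np.random.default_rng(seed)
        pos = rng.normal(size=(1, 9, 3))
        g = dpd.gyration_tensor(pos)
        direct = np.mean(np.sum((pos[0] - pos[0].mean(axis=0)) ** 2, axis=1))
        assert np.trace(g.tensors[0]) == pytest.approx(direct, rel=1e-12)
        assert g.rg[0] ** 2 == pytest.approx(direct, rel=1e-12)

    @settings(derandomize=True, max_examples=20, deadline=None)
    @given(seed=st.integers(0, 10 ** 6))
    def test_shape_factor_rotation_invariant(self, seed):
        rng = np.random.default_rng(seed)
        pos = rng.normal(size=(9, 3))
        rot = Rotation.random(random_state=seed).as_matrix()
        g1 = dpd.gyration_tensor(chain(pos))
        g2 = dpd.gyration_tensor(chain(pos @ rot.T))
        assert g2.delta[0] == pytest.approx(g1.delta[0], rel=1e-9)
        assert g2.rg[0] == pytest.approx(g1.rg[0], rel=1e-12)

    def test_invariant_under_translation_and_rewrap(self, lipid_template):
        rng = np.random.default_rng(4)
        box = np.full(3, 6.0)
        pos = 3.0 + rng.normal(scale=0.4, size=(1, 11, 3))
        g1 = dpd.gyration_tensor(pos, box=box, parent=lipid_template.parent)
        shifted = np.mod(pos + np.array([5.0, 2.7, 4.4]), box)
        g2 = dpd.gyration_tensor(shifted, box=box, parent=lipid_template.parent)
        assert np.allclose(g1.tensors, g2.tensors, atol=1e-12)

    def test_unwrap_restores_chain_split_by_boundary(self, lipid_template):
        # straight chain along x crossing the periodic face
        box = np.full(3, 6.0)
        xs = np.mod(5.5 + 0.7 * np.arange(11), 6.0)
        pos = np.zeros((1, 11, 3))
        pos[0, :, 0] = xs
        pos[0, :, 1:] = 3.0
        # walk order: bead k bonded to parent; straight head + both tails at x
        g = dpd.gyration_tensor(pos, box=box, parent=np.arange(-1, 10))
        assert g.rg[0] == pytest.approx(np.std(0.7 * np.arange(11)), rel=1e-12)


class TestShapeFactor:
    def test_sphere_is_zero(self):
        assert dpd.shape_factor(2.0, 2.0, 2.0) == pytest.approx(0.0, abs=1e-15)

    def test_rod_is_one(self):
        assert dpd.shape_factor(0.0, 0.0, 3.0) == pytest.approx(1.0)

    def test_planar_disc_is_quarter(self):
        assert dpd.shape_factor(0.0, 1.3, 1.3) == pytest.approx(0.25)

    def test_bounds(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            v = rng.uniform(0, 5, 3)
            assert 0.0 <= dpd.shape_factor(*v) <= 1.0 + 1e-12

    def test_point_chain_rejected(self):
        with pytest.raises(ValueError):
            dpd.shape_factor(0.0, 0.0, 0.0)
        with pytest.raises(ValueError):
            dpd.shape_factor(-1.0, 1.0, 1.0)


class TestMeanRadiusOfGyration:
    def test_chain_mean_of_scalars(self):
        # two rigid chains with Rg = 1 and 3 -> chain-mean 2
        c1 = np.array([[-1, 0, 0], [1, 0, 0]], float)
        c3 = np.array([[-3, 0, 0], [3, 0, 0]], float)
        g = dpd.gyration_tensor(np.stack([c1, c3]))
        assert g.mean_rg == pytest.approx(2.0)

    def test_stationary_series_level(self):
        df = pd.DataFrame({"time": np.arange(100.0),
                           "rg_mean": np.full(100, 2.5)})
        out = dpd.mean_radius_of_gyration(df)
        assert out["rg_mean"] == pytest.approx(2.5)

    def test_empty_window_rejected(self):
        with pytest.raises(ValueError):
            dpd.mean_radius_of_gyration(
                pd.DataFrame({"time": [], "rg_mean": []}))


class TestMeanFlowVelocity:
    def test_zero_shear_equilibrium_is_small(self):
        st_ = dpd.water_only(10.0, 3.0, seed=1)   # 150 beads per slab
        dpd.init_velocities(st_, 1.0, seed=2)
        # slab-mean folding cancels thermal motion: ~|N(0, 1/sqrt(150))|
        assert mean_flow_velocity_frame(st_) < 0.15

    def test_folded_sawtooth_level(self):
        # ideal triangle-wave profile of branch slope g: mean |vx| = g Lz / 8
        g, lz = 0.06, 10.0
        z = np.linspace(0, lz, 4000, endpoint=False)
        vmax = g * lz / 4
        vx = np.where(z < lz / 2, vmax - g * z, -vmax + g * (z - lz / 2))
        pos = np.zeros((z.size, 3))
        pos[:, 2] = z
        vel = np.zeros((z.size, 3))
        vel[:, 0] = vx
        st_ = dpd.SystemState(positions=pos, velocities=vel,
                              species=np.full(z.size, 2, np.int8),
                              box=np.full(3, lz))
        assert mean_flow_velocity_frame(st_) == pytest.approx(g * lz / 8, rel=1e-2)

    def test_saturation_over_final_third(self):
        df = pd.DataFrame({"vx_mean_abs": np.concatenate(
            [np.linspace(0, 1, 60), np.full(30, 1.0)])})
        _, sat = dpd.mean_flow_velocity(df)
        assert sat == pytest.approx(1.0, abs=0.01)


class TestEnergyTrace:
    def test_ideal_gas_is_kinetic_only(self):
        st_ = dpd.water_only(5.0, 3.0, seed=1)
        dpd.init_velocities(st_, 1.0, seed=2)
        ff = dpd.ForceField(interaction=dpd.InteractionTable(
            a=np.zeros((3, 3)), sigma=0.0, gamma=0.0))
        sim = dpd.Simulation(st_, ff, config=dpd.RunConfig(n_steps=10, seed=3,
                                                           sample_every=5))
        df = sim.run().observables
        assert np.allclose(df.e_total, df.e_kinetic)
        assert df.e_kinetic.mean() == pytest.approx(1.5, rel=0.05)

    def test_plateau_of_stationary_noisy_series(self):
        rng = np.random.default_rng(0)
        t = np.arange(0.0, 1000.0, 1.0)
        v = 7.6 + rng.normal(scale=0.005, size=t.size)
        p = detect_plateau(t, v, window=200.0, slope_tol=1e-4)
        assert p.mean == pytest.approx(7.6, abs=0.01)
        assert p.onset_time == 0.0

    def test_knee_detection_on_relaxing_series(self):
        t = np.arange(0.0, 2000.0, 1.0)
        knee = 800.0
        v = np.where(t < knee, 9.0 - (9.0 - 7.6) * t / knee, 7.6)
        p = detect_plateau(t, v, window=200.0, slope_tol=1e-4)
        assert p.onset_time == pytest.approx(knee, rel=0.05)
        assert p.mean == pytest.approx(7.6, abs=0.01)

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError):
            detect_plateau(np.arange(10.0), np.ones(10), window=200.0)


class TestClusterAggregates:
    def lipid_gas(self, centers, box=20.0):
        pos = np.concatenate([np.asarray(c) + 0.3 * np.arange(3)[:, None] * [1, 0, 0]
                              for c in centers])
        n = pos.shape[0]
        return dpd.SystemState(positions=np.mod(pos, box),
                               velocities=np.zeros((n, 3)),
                               species=np.full(n, 1, np.int8),  # all tails
                               box=np.full(3, box))

    def test_two_distant_chains_two_clusters(self):
        st_ = self.lipid_gas([[2.0, 2, 2], [9.0, 9, 9]])
        _, n, _ = dpd.cluster_aggregates(st_, cutoff=1.0)
        assert n == 2

    def test_contact_chain_single_cluster(self):
        st_ = self.lipid_gas([[2.0, 2, 2], [2.9, 2, 2]])
        _, n, _ = dpd.cluster_aggregates(st_, cutoff=1.0)
        assert n == 1

    def test_dilute_gas_tiny_cutoff_all_singletons(self):
        rng = np.random.default_rng(0)
        n = 50
        st_ = dpd.SystemState(positions=rng.uniform(0, 20, (n, 3)),
                              velocities=np.zeros((n, 3)),
                              species=np.full(n, 1, np.int8),
                              box=np.full(3, 20.0))
        _, k, _ = dpd.cluster_aggregates(st_, cutoff=1e-6)
        assert k == n
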