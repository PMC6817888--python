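"""Shared fixtures: small systems and an order-independent noise oracle."""

from __future__ import annotations

import numpy as np
import pytest

import dpdshear as dpd


@pytest.fixture(scope="session")
def forcefield():
    return dpd.ForceField()


@pytest.fixture()
def small_water():
    """375-bead water box (L=5, rho=3), thermalized."""
    st = dpd.water_only(5.0, 3.0, seed=11)
    dpd.init_velocities(st, 1.0, seed=12)
    return st


@pytest.fixture(scope="session")
def lipid_template():
    return dpd.build_lipid(3, 4)


def two_bead_state(separation, box_edge=5.0, species=(2, 2), velocities=None):
    """Two beads along x at the given separation, centered in the box."""
    mid = box_edge / 2
    pos = np.array([[mid - separation / 2, mid, mid],
                    [mid + separation / 2, mid, mid]])
    vel = np.zeros((2, 3)) if velocities is None else np.asarray(velocities, float)
    return dpd.SystemState(positions=pos, velocities=vel,
                           species=np.array(species, dtype=np.int8),
                           box=np.full(3, float(box_edge)))


def numpy_pair_noise(i, j, seed):
    """Vectorized reimplementation of the counter-based pair noise.

    Independent of the compiled kernel; used as the oracle for the
    brute-force pair-sum reference.
    """
    i = np.asarray(i, dtype=np.uint64)
    j = np.asarray(j, dtype=np.uint64)
    lo_id = np.minimum(i, j)
    hi_id = np.maximum(i, j)
    M1 = np.uint64(0x9E3779B97F4A7C15)
    M2 = np.uint64(0xC2B2AE3D27D4EB4F)
    M3 = np.uint64(0xD6E8FEB86659FD93)
    F1 = np.uint64(0xBF58476D1CE4E5B9)
    F2 = np.uint64(0x94D049BB133111EB)
    with np.errstate(over="ignore"):
        x = lo_id * M1
        x ^= (hi_id + M2) * M2
        x ^= np.uint64(seed) * M3
        x = (x ^ (x >> np.uint64(30))) * F1
        x = (x ^ (x >> np.uint64(27))) * F2
        x ^= x >> np.uint64(31)
    u1 = ((x >> np.uint64(32)).astype(np.float64) + 0.5) / 2.0 ** 32
    u2 = ((x & np.uint64(0xFFFFFFFF)).astype(np.float64) + 0.5) / 2.0 ** 32
    return np.sqrt(-2.0 * np.log(u1)) * np.cos(2.0 * np.pi * u2)


def brute_force_pair_forces(state, table, dt, seed):
    """O(N^2) numpy reference for all three DPD pair channels."""
    pos, vel, box = state.positions, state.velocities, state.box
    n = state.n
    d = pos[:, None, :] - pos[None, :, :]
    d -= box * np.round(d / box)
    r = np.linalg.norm(d, axis=2)
    iu, ju = np.triu_indices(n, 1)
    mask = r[iu, ju] < table.r_c
    ii, jj = iu[mask], ju[mask]
    rij = r[ii, jj]
    rhat = d[ii, jj] / rij[:, None]
    w = 1.0 - rij / table.r_c
    aij = table.a[state.species[ii], state.species[jj]]
    vij = vel[ii] - vel[jj]
    zeta = numpy_pair_noise(ii, jj, seed)
    fmag = (aij * w
            - table.gamma * w ** 2 * np.einsum("ij,ij->i", rhat, vij)
            + table.sigma * w * zeta / np.sqrt(dt))
    forces = np.zeros_like(pos)
    np.add.at(forces, ii, fmag[:, None] * rhat)
    np.subtract.at(forces, jj, fmag[:, None] * rhat)
    energy = float(np.sum(0.5 * aij * table.r_c * w ** 2))
    return forces, energy
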