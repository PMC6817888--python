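"""Python-facing force evaluation: DPD pair forces, bonds, angles, neighbor search.

These wrap the compiled kernels in :mod:`dpdshear._kernels`; the integrator
calls the kernels directly.  All routines use minimum-image geometry in an
orthorhombic periodic box and accumulate into per-bead force arrays.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np

from . import _kernels
from .forcefield import InteractionTable
from .state import SystemState

log = logging.getLogger(__name__)


def weight(r, r_c: float = 1.0):
    """DPD weight function w(r) = 1 - r/r_c inside the cutoff, else 0."""
    r = np.asarray(r, dtype=np.float64)
    if np.any(r < 0):
        raise ValueError("separation r must be non-negative")
    w = np.where(r < r_c, 1.0 - r / r_c, 0.0)
    return float(w) if w.ndim == 0 else w


def pair_forces(state: SystemState, table: InteractionTable, dt: float = 0.01,
                seed: int = 0):
    """All three DPD pair channels for one configuration.

    Returns ``(forces, energy)`` where ``energy`` is the conservative pair
    energy sum((a_ij r_c / 2)(1 - r/r_c)^2).  The noise is determined by
    ``seed`` (one symmetric Gaussian per pair).  Exactly-overlapping beads
    get a pseudo-random force direction and are logged.
    """
    forces = np.zeros_like(state.positions)
    e, nov = _kernels.nonbonded_forces(
        state.positions, state.velocities, state.species, state.box,
        table.a, table.gamma, table.sigma, table.r_c,
        1.0 / np.sqrt(dt), int(seed), forces)
    if nov:
        log.warning("%d exactly-overlapping pair(s): random force direction used", nov)
    return forces, e


def bond_forces(state: SystemState, bonds: np.ndarray, k_bond: float,
                r_bond: float):
    """Harmonic bond forces F = k_s (1 - r/r_s) r_hat; returns (forces, energy)."""
    forces = np.zeros_like(state.positions)
    bonds = np.ascontiguousarray(bonds, dtype=np.int64).reshape(-1, 2)
    e, nov = _kernels.bond_forces_kernel(
        state.positions, state.box, bonds, float(k_bond), float(r_bond), forces)
    if nov:
        log.warning("%d zero-length bond(s): random force direction used", nov)
    return forces, e


def angle_forces(state: SystemState, angles: np.ndarray, theta0: np.ndarray,
                 k_angle: float):
    """Harmonic angle forces from U = k_theta (theta - theta0)^2.

    Returns (forces, energy).  Triples with a zero-length arm are rejected:
    the bending angle is undefined there.
    """
    angles = np.ascontiguousarray(angles, dtype=np.int64).reshape(-1, 3)
    theta0 = np.ascontiguousarray(theta0, dtype=np.float64)
    forces = np.zeros_like(state.positions)
    e, ndeg = _kernels.angle_forces_kernel(
        state.positions, state.box, angles, theta0, float(k_angle), forces)
    if ndeg:
        raise ValueError(f"{ndeg} angle triple(s) with a zero-length arm")
    return forces, e


def neighbor_pairs(positions: np.ndarray, box: np.ndarray, r_c: float = 1.0,
                   force_brute: bool = False):
    """Every unordered pair with minimum-image distance < r_c, exactly once.

    Uses a linked-cell search; boxes narrower than 3 r_c on any axis fall
    back to the O(N^2) double loop with a warning.
    """
    positions = np.ascontiguousarray(positions, dtype=np.float64).reshape(-1, 3)
    box = np.asarray(box, dtype=np.float64).reshape(3)
    n = positions.shape[0]
    if not force_brute and np.any(box // r_c < 3):
        warnings.warn("box narrower than 3 r_c on some axis: brute-force pair search",
                      stacklevel=2)
    cap = max(64, n * 40)
    while True:
        out_i = np.empty(cap, dtype=np.int64)
        out_j = np.empty(cap, dtype=np.int64)
        cnt = _kernels.neighbor_pairs_kernel(positions, box, float(r_c),
                                             out_i, out_j, force_brute)
        if cnt >= 0:
            pi, pj = out_i[:cnt], out_j[:cnt]
            lo = np.minimum(pi, pj)
            hi = np.maximum(pi, pj)
            return lo, hi
        cap *= 2
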