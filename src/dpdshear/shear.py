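"""Reverse non-equilibrium shear: slab momentum swaps and velocity profiles.

Shear is imposed by the momentum-swap (flip) scheme: the box is divided into
``n_slabs`` equal slabs along z; every ``W`` steps the bead with the most
negative v_x in the slab at z = 0 exchanges its v_x with the bead with the
most positive v_x in the slab at z = L_z/2.  The swap leaves positions,
total momentum and kinetic energy untouched while carrying a known x-momentum
flux j_z(p_x) = p_x / (2 t L_x L_y) across the z-planes; the fluid responds
with a sawtooth v_x(z) profile whose branch slope is the shear rate
gamma_dot = dv_x/dz.  Smaller W means stronger shear.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .state import SystemState

log = logging.getLogger(__name__)


@dataclass
class ShearProtocol:
    """Swap schedule and momentum bookkeeping (shear axis x, gradient axis z)."""

    W: int = 5
    n_slabs: int = 20
    accumulated_px: float = 0.0
    swap_log: list = field(default_factory=list)   # (step, dpx) tuples

    def __post_init__(self):
        if self.W < 1:
            raise ValueError("swap interval W must be >= 1")
        if self.n_slabs < 2 or self.n_slabs % 2:
            raise ValueError("n_slabs must be even and >= 2")

    @property
    def lower_slab(self) -> int:
        return 0

    @property
    def upper_slab(self) -> int:
        return self.n_slabs // 2


def assign_slabs(state: SystemState, n_slabs: int) -> np.ndarray:
    """Slab index per bead: z in [k Lz/n, (k+1) Lz/n) -> k."""
    lz = state.box[2]
    idx = np.floor(state.positions[:, 2] * n_slabs / lz).astype(np.int64)
    return np.clip(idx, 0, n_slabs - 1)


def momentum_swap(state: SystemState, protocol: ShearProtocol) -> float:
    """Exchange v_x between the extreme beads of the two driven slabs.

    Picks the most negative v_x in the lower slab (z ~ 0) and the most
    positive v_x in the upper slab (z ~ L_z/2) and swaps their x-velocities.
    With equal masses this conserves total momentum and kinetic energy
    exactly.  Returns the transferred momentum dpx = m (vx_up - vx_lo);
    an empty designated slab skips the swap (returns 0) with a warning.
    """
    slabs = assign_slabs(state, protocol.n_slabs)
    lower = np.flatnonzero(slabs == protocol.lower_slab)
    upper = np.flatnonzero(slabs == protocol.upper_slab)
    if lower.size == 0 or upper.size == 0:
        log.warning("step %d: empty swap slab, momentum swap skipped", state.step)
        return 0.0
    vx = state.velocities[:, 0]
    i_lo = lower[np.argmin(vx[lower])]
    i_up = upper[np.argmax(vx[upper])]
    dpx = state.mass * (vx[i_up] - vx[i_lo])
    vx[i_lo], vx[i_up] = vx[i_up], vx[i_lo]
    protocol.accumulated_px += dpx
    protocol.swap_log.append((state.step, float(dpx)))
    return float(dpx)


def momentum_flux(p_x: float, t: float, L_x: float, L_y: float) -> float:
    """Imposed momentum flux j_z(p_x) = p_x / (2 t L_x L_y).

    The factor 2 reflects the two equivalent flux planes of the periodic box.
    """
    if t <= 0:
        raise ValueError("elapsed time must be positive")
    if L_x <= 0 or L_y <= 0:
        raise ValueError("box cross-section must be positive")
    return p_x / (2.0 * t * L_x * L_y)


@dataclass
class VelocityProfile:
    """Slab-resolved mean x-velocity: centers z_k, <v_x>(z_k), sample counts."""

    z: np.ndarray
    vx: np.ndarray
    counts: np.ndarray
    box: np.ndarray = None

    def __post_init__(self):
        self.z = np.asarray(self.z, dtype=np.float64)
        self.vx = np.asarray(self.vx, dtype=np.float64)
        self.counts = np.asarray(self.counts)

    @property
    def n_slabs(self) -> int:
        return self.z.size


@dataclass(frozen=True)
class ShearRateFit:
    """Least-squares branch slopes of a sawtooth profile."""

    shear_rate: float          # mean |slope| over the two branches
    slopes: tuple              # signed slopes (lower branch, upper branch)
    r_squared: tuple
    residual: float            # rms residual of both fits


def measure_shear_rate(profile: VelocityProfile, exclude_swap_slabs: bool = True
                       ) -> ShearRateFit:
    """Fit dv_x/dz on each monotone branch of the sawtooth profile.

    The two branches run between the swap slabs at k = 0 and k = n/2; those
    two slabs are excluded from the fits by default because the swaps
    perturb them.  Returns the mean absolute slope (the shear rate).
    """
    n = profile.n_slabs
    if n < 8:
        raise ValueError("need at least 8 slabs to fit two branches")
    half = n // 2
    lo = np.arange(1, half) if exclude_swap_slabs else np.arange(0, half + 1)
    up = np.arange(half + 1, n) if exclude_swap_slabs else np.arange(half, n)
    fits = []
    for idx in (lo, up):
        idx = idx[profile.counts[idx] > 0]
        z = profile.z[idx]
        if z.size < 3 or np.ptp(z) == 0:
            raise ValueError("degenerate profile: too few populated slabs per branch")
        res = stats.linregress(z, profile.vx[idx])
        pred = res.intercept + res.slope * z
        fits.append((res.slope, res.rvalue ** 2,
                     float(np.sqrt(np.mean((profile.vx[idx] - pred) ** 2)))))
    slopes = (fits[0][0], fits[1][0])
    return ShearRateFit(
        shear_rate=0.5 * (abs(slopes[0]) + abs(slopes[1])),
        slopes=slopes,
        r_squared=(fits[0][1], fits[1][1]),
        residual=0.5 * (fits[0][2] + fits[1][2]),
    )


class ProfileAccumulator:
    """Accumulate per-slab v_x sums over sample frames (after a warmup)."""

    def __init__(self, n_slabs: int, box: np.ndarray):
        self.n_slabs = int(n_slabs)
        self.box = np.asarray(box, dtype=np.float64)
        self._vx = np.zeros(self.n_slabs)
        self._n = np.zeros(self.n_slabs, dtype=np.int64)

    def add(self, state: SystemState) -> None:
        slabs = assign_slabs(state, self.n_slabs)
        np.add.at(self._vx, slabs, state.velocities[:, 0])
        np.add.at(self._n, slabs, 1)

    def profile(self) -> VelocityProfile:
        lz = self.box[2]
        z = (np.arange(self.n_slabs) + 0.5) * lz / self.n_slabs
        with np.errstate(invalid="ignore"):
            vx = np.where(self._n > 0, self._vx / np.maximum(self._n, 1), np.nan)
        return VelocityProfile(z=z, vx=vx, counts=self._n.copy(), box=self.box.copy())
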