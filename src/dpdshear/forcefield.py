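"""DPD interaction parameters.

The pairwise force on bead i from bead j has three channels inside the
cutoff r_c (w(r) = 1 - r/r_c):

    F^C = a_ij w(r) r_hat                      soft repulsion
    F^D = -gamma w(r)^2 (r_hat . v_ij) r_hat   pair friction
    F^R = sigma w(r) zeta_ij dt^{-1/2} r_hat   thermal noise

The dissipative and random channels form a momentum-conserving thermostat;
the fluctuation--dissipation theorem fixes sigma^2 = 2 gamma kBT.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .topology import HEAD, TAIL, WATER

#: default maximum repulsions: hydrophobically incompatible pairs (H-T, W-T)
#: repel strongly; all compatible pairs share the weak baseline.
A_LIKE = 50.0
A_UNLIKE = 200.0


def repulsion_matrix(a_like: float = A_LIKE, a_unlike: float = A_UNLIKE) -> np.ndarray:
    """Species-by-species repulsion a_ij (order HEAD, TAIL, WATER)."""
    a = np.full((3, 3), float(a_like))
    for i, j in ((HEAD, TAIL), (WATER, TAIL)):
        a[i, j] = a[j, i] = float(a_unlike)
    return a


@dataclass(frozen=True)
class InteractionTable:
    """Nonbonded DPD parameters; sigma and gamma obey sigma^2 = 2 gamma kBT."""

    a: np.ndarray = field(default_factory=repulsion_matrix)
    sigma: float = 3.0
    kBT: float = 1.0
    r_c: float = 1.0
    gamma: float = None  # derived from sigma unless given explicitly

    def __post_init__(self):
        a = np.asarray(self.a, dtype=np.float64)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError("repulsion matrix must be square")
        if not np.allclose(a, a.T):
            raise ValueError("repulsion matrix must be symmetric")
        if np.any(a < 0):
            raise ValueError("repulsions must be non-negative")
        if self.r_c <= 0:
            raise ValueError("cutoff must be positive")
        object.__setattr__(self, "a", np.ascontiguousarray(a))
        if self.gamma is None:
            object.__setattr__(self, "gamma", self.sigma ** 2 / (2.0 * self.kBT))
        if not np.isclose(self.sigma ** 2, 2.0 * self.gamma * self.kBT):
            raise ValueError("fluctuation-dissipation violated: sigma^2 != 2 gamma kBT")


@dataclass(frozen=True)
class ForceField:
    """Nonbonded table plus bonded constants (theta0 lives with the topology)."""

    interaction: InteractionTable = field(default_factory=InteractionTable)
    k_bond: float = 100.0
    r_bond: float = 0.7
    k_angle: float = 6.0

    def __post_init__(self):
        if self.k_bond < 0 or self.k_angle < 0:
            raise ValueError("force constants must be non-negative")
        for v in (self.k_bond, self.r_bond, self.k_angle):
            if not np.isfinite(v):
                raise ValueError("force-field constants must be finite")
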