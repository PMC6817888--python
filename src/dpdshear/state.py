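"""System state container (positions, velocities, forces, species, box)."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class SystemState:
    """All per-bead dynamical data plus the periodic box.

    Units are reduced DPD units: lengths in the cutoff r_c, energies in kBT,
    masses in the bead mass m (= 1), time in tau = r_c * sqrt(m / kBT).
    Positions are kept wrapped to [0, L) per axis.
    """

    positions: np.ndarray        # (n, 3)
    velocities: np.ndarray       # (n, 3)
    species: np.ndarray          # (n,) int8
    box: np.ndarray              # (3,) edge lengths
    forces: np.ndarray = None    # (n, 3)
    mass: float = 1.0
    step: int = 0
    time: float = 0.0

    def __post_init__(self):
        self.positions = np.ascontiguousarray(self.positions, dtype=np.float64)
        self.velocities = np.ascontiguousarray(self.velocities, dtype=np.float64)
        self.species = np.ascontiguousarray(self.species, dtype=np.int8)
        self.box = np.asarray(self.box, dtype=np.float64).reshape(3)
        if self.forces is None:
            self.forces = np.zeros_like(self.positions)
        else:
            self.forces = np.ascontiguousarray(self.forces, dtype=np.float64)

    @property
    def n(self) -> int:
        return self.positions.shape[0]

    @property
    def volume(self) -> float:
        return float(np.prod(self.box))

    def wrap(self) -> None:
        """Wrap positions into [0, L) per axis (in place)."""
        np.mod(self.positions, self.box, out=self.positions)

    def validate(self) -> None:
        n = self.n
        if not (self.velocities.shape == (n, 3) and self.forces.shape == (n, 3)
                and self.species.shape == (n,)):
            raise ValueError("inconsistent array lengths in SystemState")
        for name in ("positions", "velocities", "forces", "box"):
            if not np.all(np.isfinite(getattr(self, name))):
                raise ValueError(f"non-finite values in {name}")
        if np.any(self.positions < 0) or np.any(self.positions >= self.box):
            raise ValueError("positions not wrapped to [0, L)")

    def momentum(self) -> np.ndarray:
        return self.mass * self.velocities.sum(axis=0)

    def kinetic_energy(self) -> float:
        return 0.5 * self.mass * float(np.sum(self.velocities ** 2))

    def temperature(self) -> float:
        """Kinetic temperature with 3N - 3 degrees of freedom (COM removed)."""
        dof = 3 * self.n - 3
        if dof <= 0:
            return 0.0
        return 2.0 * self.kinetic_energy() / dof

    def copy(self) -> "SystemState":
        return SystemState(
            positions=self.positions.copy(), velocities=self.velocities.copy(),
            species=self.species.copy(), box=self.box.copy(),
            forces=self.forces.copy(), mass=self.mass,
            step=self.step, time=self.time,
        )
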