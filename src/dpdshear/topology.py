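"""Coarse-grained lipid architecture and solvated-system composition.

The lipid is a double-tailed amphiphile: a linear chain of ``n_head``
hydrophilic head beads (H) with two linear tails of ``n_tail`` hydrophobic
beads (T) each, both tails bonded to the last head bead.  Consecutive beads
are joined by harmonic bonds F = k_s (1 - r/r_s) r_hat; bending stiffness is
applied through harmonic angle terms k_theta (theta - theta0)^2 with
theta0 = pi for three consecutive tail beads and theta0 = 2*pi/3 for the
head-internal and head--tail junction triples.

All lengths are in units of the interaction cutoff r_c, energies in kBT.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: integer species codes used throughout the package
HEAD, TAIL, WATER = 0, 1, 2
SPECIES_LABELS = {HEAD: "H", TAIL: "T", WATER: "W"}
#: species codes used in exported files (LAMMPS convention, 1-based)
EXPORT_TYPE = {HEAD: 1, TAIL: 2, WATER: 3}

TWO_THIRDS_PI = 2.0 * np.pi / 3.0


@dataclass(frozen=True)
class LipidTopology:
    """Bonded structure of a single lipid chain.

    Bead order is canonical: H_1..H_nh, then tail A T_1..T_nt, then tail B
    T_1..T_nt.  ``parent[i]`` is the bonded predecessor of bead ``i`` in that
    order (-1 for the first bead); it defines the walk used to unwrap a chain
    across periodic images.
    """

    n_head: int
    n_tail: int
    species: np.ndarray          # (n_beads,) int8, HEAD/TAIL
    bonds: np.ndarray            # (n_bonds, 2) int64
    angles: np.ndarray           # (n_angles, 3) int64, middle bead second
    theta0: np.ndarray           # (n_angles,) float64, radians
    parent: np.ndarray           # (n_beads,) int64
    k_bond: float = 100.0
    r_bond: float = 0.7
    k_angle: float = 6.0

    @property
    def n_beads(self) -> int:
        return self.n_head + 2 * self.n_tail

    def __post_init__(self):
        nh, nt = self.n_head, self.n_tail
        assert int(np.sum(self.species == HEAD)) == nh
        assert int(np.sum(self.species == TAIL)) == 2 * nt
        assert self.bonds.shape[0] == self.n_beads - 1  # connected, acyclic


def build_lipid(n_head: int, n_tail: int, *, k_bond: float = 100.0,
                r_bond: float = 0.7, k_angle: float = 6.0) -> LipidTopology:
    """Build the double-tailed lipid template.

    Parameters
    ----------
    n_head, n_tail
        Number of head beads and beads per tail; both must be >= 2 so that
        the junction triples exist.

    Notes
    -----
    Angle terms: every head-internal consecutive triple (all H) and the two
    junction triples (H_{nh-1}, H_nh, T_1 of each tail) get theta0 = 2*pi/3;
    every three consecutive beads inside one tail get theta0 = pi.
    """
    if n_head < 2 or n_tail < 2:
        raise ValueError(
            f"lipid needs n_head >= 2 and n_tail >= 2, got ({n_head}, {n_tail})")
    nh, nt = int(n_head), int(n_tail)
    n_beads = nh + 2 * nt

    species = np.empty(n_beads, dtype=np.int8)
    species[:nh] = HEAD
    species[nh:] = TAIL

    bonds = []
    parent = np.full(n_beads, -1, dtype=np.int64)
    for i in range(1, nh):                      # head chain
        bonds.append((i - 1, i))
        parent[i] = i - 1
    junction = nh - 1                           # last head bead
    for t in range(2):                          # two tails
        first = nh + t * nt
        bonds.append((junction, first))
        parent[first] = junction
        for j in range(1, nt):
            bonds.append((first + j - 1, first + j))
            parent[first + j] = first + j - 1

    angles = []
    theta0 = []
    for i in range(nh - 2):                     # head-internal HHH triples
        angles.append((i, i + 1, i + 2))
        theta0.append(TWO_THIRDS_PI)
    for t in range(2):                          # junction H,H,T triples
        first = nh + t * nt
        angles.append((junction - 1, junction, first))
        theta0.append(TWO_THIRDS_PI)
        for j in range(nt - 2):                 # tail-internal TTT triples
            angles.append((first + j, first + j + 1, first + j + 2))
            theta0.append(np.pi)

    return LipidTopology(
        n_head=nh, n_tail=nt, species=species,
        bonds=np.asarray(bonds, dtype=np.int64).reshape(-1, 2),
        angles=np.asarray(angles, dtype=np.int64).reshape(-1, 3),
        theta0=np.asarray(theta0, dtype=np.float64),
        parent=parent, k_bond=k_bond, r_bond=r_bond, k_angle=k_angle,
    )


def lipid_concentration(n_head: int, n_tail: int, n_water: int) -> float:
    """Fraction of beads belonging to lipid chains.

    phi_P = (N_HB + 2 N_TB) / (N_HB + 2 N_TB + N_WB) for one chain-equivalent
    of lipid beads per ``n_water`` water beads.
    """
    if n_head < 0 or n_tail < 0 or n_water < 0:
        raise ValueError("bead counts must be non-negative")
    lipid = n_head + 2 * n_tail
    total = lipid + n_water
    if total == 0:
        raise ValueError("at least one bead count must be positive")
    return lipid / total


@dataclass(frozen=True)
class SystemComposition:
    """Bead budget of a solvated box at number density ``density``."""

    n_chains: int
    n_water: int
    total_beads: int
    phi_requested: float
    phi_realized: float
    box_edge: float
    density: float
    n_head: int = 3
    n_tail: int = 4

    @property
    def beads_per_chain(self) -> int:
        return self.n_head + 2 * self.n_tail

    def __post_init__(self):
        assert self.n_chains * self.beads_per_chain + self.n_water == self.total_beads


def compose_system(phi_p: float, box_edge: float, density: float = 3.0,
                   n_head: int = 3, n_tail: int = 4) -> SystemComposition:
    """Partition ``round(density * L^3)`` beads into lipid chains and water.

    The chain count is rounded to nearest; leftover beads become water, so
    the realized concentration deviates from the request by at most one
    chain-equivalent.
    """
    if not 0.0 <= phi_p <= 1.0:
        raise ValueError(f"phi_p must lie in [0, 1], got {phi_p}")
    if box_edge <= 0:
        raise ValueError(f"box edge must be positive, got {box_edge}")
    total = int(round(density * box_edge ** 3))
    per_chain = n_head + 2 * n_tail
    n_chains = int(round(phi_p * total / per_chain))
    n_chains = min(n_chains, total // per_chain)
    n_water = total - n_chains * per_chain
    phi_real = lipid_concentration(n_chains * n_head, n_chains * n_tail, n_water) \
        if total else 0.0
    return SystemComposition(
        n_chains=n_chains, n_water=n_water, total_beads=total,
        phi_requested=float(phi_p), phi_realized=phi_real,
        box_edge=float(box_edge), density=float(density),
        n_head=n_head, n_tail=n_tail,
    )


@dataclass(frozen=True)
class SystemTopology:
    """Bonded structure of the whole box: ``n_chains`` copies of a template.

    Chains occupy beads ``[c * n_beads, (c+1) * n_beads)`` for chain ``c``;
    water beads follow.  ``bonds``/``angles`` are global bead indices.
    """

    template: LipidTopology | None
    n_chains: int
    bonds: np.ndarray
    angles: np.ndarray
    theta0: np.ndarray

    @property
    def beads_per_chain(self) -> int:
        return self.template.n_beads if self.template is not None else 0

    @property
    def n_lipid_beads(self) -> int:
        return self.n_chains * self.beads_per_chain

    def chain_positions(self, positions: np.ndarray) -> np.ndarray:
        """View lipid bead positions as (n_chains, beads_per_chain, 3)."""
        nb = self.beads_per_chain
        return positions[: self.n_chains * nb].reshape(self.n_chains, nb, 3)


_EMPTY_BONDS = np.empty((0, 2), dtype=np.int64)
_EMPTY_ANGLES = np.empty((0, 3), dtype=np.int64)
_EMPTY_THETA0 = np.empty(0, dtype=np.float64)


def replicate_topology(template: LipidTopology | None, n_chains: int) -> SystemTopology:
    """Tile the single-chain template into global bond/angle arrays."""
    if template is None or n_chains == 0:
        return SystemTopology(template=template, n_chains=int(n_chains),
                              bonds=_EMPTY_BONDS, angles=_EMPTY_ANGLES,
                              theta0=_EMPTY_THETA0)
    nb = template.n_beads
    offsets = (np.arange(n_chains, dtype=np.int64) * nb)[:, None, None]
    bonds = (template.bonds[None, :, :] + offsets).reshape(-1, 2)
    angles = (template.angles[None, :, :] + offsets).reshape(-1, 3)
    theta0 = np.tile(template.theta0, n_chains)
    return SystemTopology(template=template, n_chains=int(n_chains),
                          bonds=bonds, angles=angles, theta0=theta0)
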