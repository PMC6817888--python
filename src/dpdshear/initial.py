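"""Synthetic starting configurations.

Three builders cover the study conditions: a random solvated lipid solution
(the self-assembly starting point), a pure water box (thermostat and
viscosity fixtures), and an idealized porous-cylinder state -- lipids
arranged as an annular hydrophobic matrix around polygonally placed
water-filled channels -- for scaled-down shear experiments.  All builders
are pure functions of their recipe and seed; soft DPD cores make explicit
overlap removal unnecessary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .state import SystemState
from .topology import (WATER, LipidTopology, build_lipid, compose_system,
                       replicate_topology)

#: pore layout per pore count: polygonal arrangement about the cylinder axis
POLYGON_NAMES = {3: "triangular", 4: "quadrangular", 5: "pentagonal", 6: "hexagonal"}


@dataclass(frozen=True)
class ConfigRecipe:
    """Declarative description of a starting configuration."""

    kind: str = "random_solution"     # random_solution | water_only | porous_cylinder
    phi_p: float = 0.35
    box_edge: float = 30.0
    density: float = 3.0
    n_head: int = 3
    n_tail: int = 4
    seed: int = 0
    n_pores: int = 3
    pore_radius_ratio: float = 0.22   # pore radius / outer radius
    pore_center_ratio: float = 0.55   # pore-center ring radius / outer radius

    def __post_init__(self):
        if self.kind not in ("random_solution", "water_only", "porous_cylinder"):
            raise ValueError(f"unknown recipe kind {self.kind!r}")
        if not 0.0 <= self.phi_p <= 1.0:
            raise ValueError("phi_p must lie in [0, 1]")
        if self.kind == "porous_cylinder":
            if self.n_pores not in POLYGON_NAMES:
                raise ValueError("n_pores must be one of 3, 4, 5, 6")
            # pores must fit inside the outer radius and not overlap
            c, d = self.pore_radius_ratio, self.pore_center_ratio
            if d + c >= 1.0:
                raise ValueError("pores do not fit inside the outer cylinder")
            if 2 * d * np.sin(np.pi / self.n_pores) <= 2 * c:
                raise ValueError("pore channels overlap each other")
            if self.n_pores * c ** 2 >= 1.0:
                raise ValueError("pore area exceeds the cylinder cross-section")


def build(recipe: ConfigRecipe):
    """Materialize a recipe into (SystemState, SystemTopology)."""
    if recipe.kind == "water_only":
        state = water_only(recipe.box_edge, recipe.density, recipe.seed)
        return state, replicate_topology(None, 0)
    if recipe.kind == "random_solution":
        return random_solution(recipe)
    return porous_cylinder(recipe)


def water_only(box_edge: float, density: float = 3.0, seed: int = 0) -> SystemState:
    """Uniform box of round(density * L^3) water beads."""
    if box_edge <= 0 or density <= 0:
        raise ValueError("box edge and density must be positive")
    n = int(round(density * box_edge ** 3))
    rng = np.random.default_rng(seed)
    box = np.full(3, float(box_edge))
    return SystemState(
        positions=rng.uniform(0.0, box_edge, size=(n, 3)),
        velocities=np.zeros((n, 3)),
        species=np.full(n, WATER, dtype=np.int8),
        box=box)


def _random_walk_chains(template: LipidTopology, n_chains: int, box: np.ndarray,
                        rng: np.random.Generator) -> np.ndarray:
    """Chains as random walks of step r_bond, reflected at the box walls."""
    nb = template.n_beads
    pos = np.empty((n_chains, nb, 3))
    pos[:, 0, :] = rng.uniform(0.0, 1.0, size=(n_chains, 3)) * box
    steps = rng.normal(size=(n_chains, nb, 3))
    steps /= np.linalg.norm(steps, axis=2, keepdims=True)
    for k in range(1, nb):
        p = template.parent[k]
        pos[:, k, :] = pos[:, p, :] + template.r_bond * steps[:, k, :]
    # reflect escapes back into the box, then wrap (no-op after reflection
    # as long as chains are shorter than L)
    for _ in range(3):
        pos = np.where(pos < 0, -pos, pos)
        pos = np.where(pos >= box, 2 * box - pos, pos)
    return np.mod(pos, box)


def _assemble(template, chain_pos, n_water, box, rng):
    n_chains = chain_pos.shape[0]
    species = np.concatenate([
        np.tile(template.species, n_chains) if n_chains else
        np.empty(0, dtype=np.int8),
        np.full(n_water, WATER, dtype=np.int8)])
    positions = np.concatenate([
        chain_pos.reshape(-1, 3),
        rng.uniform(0.0, 1.0, size=(n_water, 3)) * box])
    state = SystemState(positions=positions,
                        velocities=np.zeros_like(positions),
                        species=species, box=box)
    state.wrap()
    return state, replicate_topology(template, n_chains)


def random_solution(recipe: ConfigRecipe):
    """Randomly solvated lipid solution matching compose_system exactly."""
    comp = compose_system(recipe.phi_p, recipe.box_edge, recipe.density,
                          recipe.n_head, recipe.n_tail)
    template = build_lipid(recipe.n_head, recipe.n_tail)
    rng = np.random.default_rng(recipe.seed)
    box = np.full(3, float(recipe.box_edge))
    chain_pos = _random_walk_chains(template, comp.n_chains, box, rng) \
        if comp.n_chains else np.empty((0, template.n_beads, 3))
    return _assemble(template, chain_pos, comp.n_water, box, rng)


def porous_cylinder(recipe: ConfigRecipe):
    """Idealized porous-cylinder state: T matrix, H-coated interfaces.

    A large lipid cylinder along z contains ``n_pores`` water channels whose
    centers form a regular polygon about the axis.  The outer radius is set
    so the annular lipid matrix occupies the fraction phi_p of the
    cross-section; chains stand on the interfaces with heads on the water
    side and tails pointing into the matrix, so every head bead sits within
    about one bead diameter of a lipid--water interface by construction.
    """
    if recipe.kind != "porous_cylinder":
        recipe = ConfigRecipe(**{**recipe.__dict__, "kind": "porous_cylinder"})
    comp = compose_system(recipe.phi_p, recipe.box_edge, recipe.density,
                          recipe.n_head, recipe.n_tail)
    template = build_lipid(recipe.n_head, recipe.n_tail)
    rng = np.random.default_rng(recipe.seed)
    L = float(recipe.box_edge)
    box = np.full(3, L)
    n = recipe.n_pores
    # outer radius from area balance: pi R^2 (1 - n c^2) = phi_p L^2
    c = recipe.pore_radius_ratio
    r_out = np.sqrt(recipe.phi_p * L * L / (np.pi * (1.0 - n * c * c)))
    if r_out >= L / 2:
        raise ValueError("outer cylinder does not fit in the box")
    r_pore = c * r_out
    d_ring = recipe.pore_center_ratio * r_out
    centre = np.array([L / 2, L / 2])
    pore_angles = 2 * np.pi * np.arange(n) / n
    pore_centres = centre + d_ring * np.stack(
        [np.cos(pore_angles), np.sin(pore_angles)], axis=1)

    rs = template.r_bond
    nh, nt = recipe.n_head, recipe.n_tail
    nch = comp.n_chains
    # surface selection weighted by interface area (outer vs each pore)
    weights = np.array([r_out] + [r_pore] * n, dtype=float)
    weights /= weights.sum()
    surf = rng.choice(n + 1, size=nch, p=weights)
    phi = rng.uniform(0.0, 2 * np.pi, size=nch)
    zc = rng.uniform(0.0, L, size=nch)
    radial = np.stack([np.cos(phi), np.sin(phi)], axis=1)

    anchor = np.empty((nch, 2))
    normal = np.empty((nch, 2))      # unit normal pointing into the lipid matrix
    outer = surf == 0
    anchor[outer] = centre + r_out * radial[outer]
    normal[outer] = -radial[outer]
    for k in range(n):
        m = surf == k + 1
        anchor[m] = pore_centres[k] + r_pore * radial[m]
        normal[m] = radial[m]

    # chains are packed, not stretched: spacings are compressed so heads
    # hug the interface and tails fit inside the annular matrix thickness
    # (bonds relax to r_s within a few hundred steps of equilibration)
    matrix_thickness = max(r_out - d_ring - r_pore, 0.3)
    head_step = min(0.5 * rs, matrix_thickness / max(nh, 1))
    tail_step = min(rs, matrix_thickness / (nt + 1))
    chain_pos = np.empty((nch, template.n_beads, 3))
    # heads march from the water side onto the anchor (last head at anchor)
    for j in range(nh):
        off = (j - (nh - 1)) * head_step
        chain_pos[:, j, :2] = anchor + off * normal
        chain_pos[:, j, 2] = zc
    # two tails march inward, splayed sideways so they do not coincide
    perp = np.stack([-normal[:, 1], normal[:, 0]], axis=1)
    for t, side in ((0, 1.0), (1, -1.0)):
        for j in range(nt):
            k = nh + t * nt + j
            depth = (j + 1) * tail_step
            chain_pos[:, k, :2] = (anchor + depth * normal
                                   + side * 0.15 * tail_step * (j + 1) * perp)
            chain_pos[:, k, 2] = zc
    chain_pos += rng.normal(scale=0.05, size=chain_pos.shape)

    # waters fill the pores and the exterior (rejection sampling)
    n_water = comp.n_water
    waters = np.empty((0, 3))
    while waters.shape[0] < n_water:
        cand = rng.uniform(0.0, 1.0, size=(max(1024, n_water), 3)) * box
        rel = cand[:, :2] - centre
        inside_outer = np.einsum("ij,ij->i", rel, rel) < r_out ** 2
        in_pore = np.zeros(len(cand), dtype=bool)
        for pc in pore_centres:
            rel_p = cand[:, :2] - pc
            in_pore |= np.einsum("ij,ij->i", rel_p, rel_p) < r_pore ** 2
        keep = ~inside_outer | in_pore
        waters = np.concatenate([waters, cand[keep]])
    rng_water = waters[:n_water]

    species = np.concatenate([np.tile(template.species, nch),
                              np.full(n_water, WATER, dtype=np.int8)])
    positions = np.concatenate([chain_pos.reshape(-1, 3), rng_water])
    state = SystemState(positions=positions,
                        velocities=np.zeros_like(positions),
                        species=species, box=box)
    state.wrap()
    return state, replicate_topology(template, nch)
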