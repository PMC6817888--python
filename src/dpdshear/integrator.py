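"""NVT time integration with the Groot--Warren modified velocity Verlet.

One step of size dt advances

    r <- r + dt v + dt^2 f / 2
    v~ <- v + lambda dt f          (velocity prediction, lambda = 0.65)
    f' <- F(r, v~)                 (dissipative force uses the prediction)
    v <- v + dt (f + f') / 2

with positions re-wrapped into the periodic box.  The momentum-swap shear
protocol, when active, fires before integration at steps divisible by W.
Forces are evaluated once per step; the counter-based pair noise makes a run
a pure function of (initial state, seed).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import _kernels, observables
from .forcefield import ForceField
from .shear import ProfileAccumulator, ShearProtocol, momentum_swap
from .state import SystemState
from .topology import SystemTopology, replicate_topology

log = logging.getLogger(__name__)

#: multiplier decorrelating per-step noise seeds from the run seed
_SEED_STRIDE = 2 ** 31


@dataclass
class RunConfig:
    """Run-control parameters (times in tau, lengths in r_c)."""

    dt: float = 0.01
    n_steps: int = 0
    seed: int = 0
    lam: float = 0.65              # Groot--Warren velocity-prediction weight
    sample_every: int = 100        # observable cadence (steps)
    frame_every: int = 0           # trajectory cadence; 0 = no frames kept
    gyration_every: int = 0        # chain-statistics cadence; 0 = off
    shear: ShearProtocol | None = None
    profile_warmup: float = 0.25   # fraction of the run before profile sampling

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.n_steps < 0:
            raise ValueError("n_steps must be >= 0")
        if self.sample_every < 1:
            raise ValueError("sample_every must be >= 1")


@dataclass
class RunResult:
    """Observable time series plus final state and shear bookkeeping."""

    observables: pd.DataFrame
    state: SystemState
    protocol: ShearProtocol | None = None
    profile: "VelocityProfile | None" = None
    frames: list | None = None


def init_velocities(state: SystemState, kBT: float = 1.0, seed: int = 0
                    ) -> SystemState:
    """Draw Maxwell--Boltzmann velocities and remove the COM drift (in place)."""
    rng = np.random.default_rng(seed)
    if kBT == 0.0:
        state.velocities[:] = 0.0
        return state
    state.velocities[:] = rng.normal(
        0.0, np.sqrt(kBT / state.mass), size=state.velocities.shape)
    state.velocities -= state.velocities.mean(axis=0)
    return state


class Simulation:
    """Drive a SystemState forward in time under a ForceField.

    Parameters
    ----------
    state
        Initial configuration (wrapped positions).
    forcefield
        Nonbonded table and bonded constants.
    topology
        Whole-box bonded structure; ``None`` means an unbonded (water) box.
    config
        Time step, step count, seed, cadences and optional shear protocol.
    """

    def __init__(self, state: SystemState, forcefield: ForceField,
                 topology: SystemTopology | None = None,
                 config: RunConfig | None = None):
        self.state = state
        self.forcefield = forcefield
        self.topology = topology if topology is not None else replicate_topology(None, 0)
        self.config = config if config is not None else RunConfig()
        self._inv_sqrt_dt = 1.0 / np.sqrt(self.config.dt)
        self._energies = None
        self._overlap_total = 0

    # -- forces ----------------------------------------------------------

    def compute_forces(self, velocities: np.ndarray | None = None) -> dict:
        """Evaluate all force channels into ``state.forces``; cache energies.

        ``velocities`` (default: the true velocities) enter the dissipative
        channel; the integrator passes the lambda-predicted velocities.
        """
        st = self.state
        vel = st.velocities if velocities is None else velocities
        table = self.forcefield.interaction
        if not np.all(np.isfinite(st.positions)):
            raise FloatingPointError(
                f"non-finite position at step {st.step}; aborting")
        st.forces[:] = 0.0
        seed = int(self.config.seed) * _SEED_STRIDE + st.step
        e_pair, nov = _kernels.nonbonded_forces(
            st.positions, vel, st.species, st.box, table.a, table.gamma,
            table.sigma, table.r_c, self._inv_sqrt_dt, seed, st.forces)
        e_bond = e_angle = 0.0
        top = self.topology
        if top.bonds.shape[0]:
            e_bond, nb_ov = _kernels.bond_forces_kernel(
                st.positions, st.box, top.bonds, self.forcefield.k_bond,
                self.forcefield.r_bond, st.forces)
            nov += nb_ov
        if top.angles.shape[0]:
            e_angle, _ = _kernels.angle_forces_kernel(
                st.positions, st.box, top.angles, top.theta0,
                self.forcefield.k_angle, st.forces)
        if nov:
            self._overlap_total += nov
            log.warning("step %d: %d overlapping pair(s)", st.step, nov)
        if not np.all(np.isfinite(st.forces)):
            raise FloatingPointError(
                f"non-finite force at step {st.step}; aborting")
        self._energies = {"e_pair": e_pair, "e_bond": e_bond, "e_angle": e_angle}
        return self._energies

    # -- stepping --------------------------------------------------------

    def step(self) -> None:
        """One modified-velocity-Verlet step (plus momentum swap if due)."""
        st, cfg = self.state, self.config
        if self._energies is None:
            self.compute_forces()
        if cfg.shear is not None and st.step % cfg.shear.W == 0:
            momentum_swap(st, cfg.shear)
        dt, lam = cfg.dt, cfg.lam
        f_old = st.forces.copy()
        st.positions += dt * st.velocities + (0.5 * dt * dt) * f_old
        st.wrap()
        v_pred = st.velocities + (lam * dt) * f_old
        st.step += 1
        st.time += dt
        self.compute_forces(v_pred)
        st.velocities += (0.5 * dt) * (f_old + st.forces)

    # -- driver ----------------------------------------------------------

    def run(self, n_steps: int | None = None) -> RunResult:
        """Advance ``n_steps`` (default: config), sampling observables.

        Observables are recorded every ``sample_every`` steps (including the
        initial and final states).  A zero-step run returns the state
        untouched.
        """
        cfg = self.config
        n_steps = cfg.n_steps if n_steps is None else int(n_steps)
        st = self.state
        rows = []
        frames = [] if cfg.frame_every else None
        prof = None
        if cfg.shear is not None:
            prof = ProfileAccumulator(cfg.shear.n_slabs, st.box)
        warmup_until = st.step + int(cfg.profile_warmup * n_steps)
        if n_steps == 0:
            return RunResult(observables=pd.DataFrame(), state=st,
                             protocol=cfg.shear, profile=None, frames=frames)
        if self._energies is None:
            self.compute_forces()

        def sample():
            row = {"step": st.step, "time": st.time,
                   "temperature": st.temperature(),
                   "e_kinetic": st.kinetic_energy() / st.n,
                   "e_pair": self._energies["e_pair"] / st.n,
                   "e_bond": self._energies["e_bond"] / st.n,
                   "e_angle": self._energies["e_angle"] / st.n,
                   "vx_mean_abs": observables.mean_flow_velocity_frame(st),
                   "px_total": float(st.momentum()[0])}
            row["e_total"] = (row["e_kinetic"] + row["e_pair"]
                              + row["e_bond"] + row["e_angle"])
            if cfg.gyration_every and self.topology.n_chains and \
                    st.step % cfg.gyration_every == 0:
                g = observables.gyration(st, self.topology)
                row.update(rg_mean=g.mean_rg, rg_xx=g.mean_rg_axis[0],
                           rg_yy=g.mean_rg_axis[1], rg_zz=g.mean_rg_axis[2],
                           delta_mean=g.mean_delta)
            rows.append(row)

        sample()
        for _ in range(n_steps):
            self.step()
            if prof is not None and st.step >= warmup_until and \
                    st.step % cfg.sample_every == 0:
                prof.add(st)
            if st.step % cfg.sample_every == 0:
                sample()
            if frames is not None and st.step % cfg.frame_every == 0:
                frames.append(st.copy())
        if rows[-1]["step"] != st.step:
            sample()
        return RunResult(observables=pd.DataFrame(rows), state=st,
                         protocol=cfg.shear,
                         profile=prof.profile() if prof is not None else None,
                         frames=frames)

    # -- persistence -----------------------------------------------------

    def save_checkpoint(self, path) -> None:
        """Full restart record (positions, velocities, forces, counters)."""
        st = self.state
        np.savez(path, positions=st.positions, velocities=st.velocities,
                 forces=st.forces, species=st.species, box=st.box,
                 step=st.step, time=st.time, mass=st.mass,
                 seed=self.config.seed)

    @staticmethod
    def load_checkpoint(path) -> SystemState:
        with np.load(path) as d:
            return SystemState(
                positions=d["positions"], velocities=d["velocities"],
                forces=d["forces"], species=d["species"], box=d["box"],
                step=int(d["step"]), time=float(d["time"]), mass=float(d["mass"]))
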