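"""Persistence: trajectory frames (LAMMPS dump and extended XYZ), flat
key=value run configuration, topology export and TSV tables.

The dump dialect is the interchange format (downstream tools parse it
natively; the reader/writer pair round-trips bit-exactly); extended XYZ is
provided for visualizers.  TSV and XYZ outputs carry a provenance header
(package version, config hash, seed).
"""

from __future__ import annotations

import hashlib
import io as _io
from dataclasses import dataclass

import numpy as np

from .state import SystemState
from .topology import EXPORT_TYPE, SPECIES_LABELS, SystemTopology

__version__ = "0.1.0"

_LABEL_TO_SPECIES = {v: k for k, v in SPECIES_LABELS.items()}
_TYPE_TO_SPECIES = {v: k for k, v in EXPORT_TYPE.items()}


@dataclass
class TrajectoryFrame:
    """One stored frame: counters, box and per-bead kinematics."""

    step: int
    time: float
    box: np.ndarray
    species: np.ndarray
    positions: np.ndarray
    velocities: np.ndarray

    @classmethod
    def from_state(cls, state: SystemState) -> "TrajectoryFrame":
        return cls(step=state.step, time=state.time, box=state.box.copy(),
                   species=state.species.copy(),
                   positions=state.positions.copy(),
                   velocities=state.velocities.copy())

    def to_state(self) -> SystemState:
        return SystemState(positions=self.positions, velocities=self.velocities,
                           species=self.species, box=self.box,
                           step=self.step, time=self.time)


# -- LAMMPS-style dump ---------------------------------------------------

def write_dump(frame, stream) -> None:
    """Write one frame in the LAMMPS dump dialect (id type x y z vx vy vz)."""
    if isinstance(frame, SystemState):
        frame = TrajectoryFrame.from_state(frame)
    w = stream.write
    w("ITEM: TIMESTEP\n%d\n" % frame.step)
    w("ITEM: NUMBER OF ATOMS\n%d\n" % len(frame.species))
    w("ITEM: BOX BOUNDS pp pp pp\n")
    for ax in range(3):
        w("%.17g %.17g\n" % (0.0, frame.box[ax]))
    w("ITEM: ATOMS id type x y z vx vy vz\n")
    for i in range(len(frame.species)):
        p = frame.positions[i]
        v = frame.velocities[i]
        w("%d %d %.17g %.17g %.17g %.17g %.17g %.17g\n"
          % (i + 1, EXPORT_TYPE[int(frame.species[i])],
             p[0], p[1], p[2], v[0], v[1], v[2]))


def _expect(line: str, prefix: str, lineno: int) -> None:
    if not line.startswith(prefix):
        raise ValueError(f"malformed dump header at line {lineno}: "
                         f"expected {prefix!r}, got {line.rstrip()!r}")


def read_dump(stream):
    """Read all frames from a dump stream; read(write(f)) == f bit-exactly."""
    frames = []
    lines = stream.read().splitlines()
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        _expect(lines[i], "ITEM: TIMESTEP", i + 1)
        step = int(lines[i + 1])
        _expect(lines[i + 2], "ITEM: NUMBER OF ATOMS", i + 3)
        n = int(lines[i + 3])
        _expect(lines[i + 4], "ITEM: BOX BOUNDS", i + 5)
        box = np.empty(3)
        for ax in range(3):
            lo, hi = (float(x) for x in lines[i + 5 + ax].split())
            box[ax] = hi - lo
        _expect(lines[i + 8], "ITEM: ATOMS id type x y z vx vy vz", i + 9)
        species = np.empty(n, dtype=np.int8)
        pos = np.empty((n, 3))
        vel = np.empty((n, 3))
        for k in range(n):
            parts = lines[i + 9 + k].split()
            idx = int(parts[0]) - 1
            species[idx] = _TYPE_TO_SPECIES[int(parts[1])]
            pos[idx] = [float(x) for x in parts[2:5]]
            vel[idx] = [float(x) for x in parts[5:8]]
        frames.append(TrajectoryFrame(step=step, time=step * 0.0, box=box,
                                      species=species, positions=pos,
                                      velocities=vel))
        i += 9 + n
    return frames


# -- extended XYZ --------------------------------------------------------

def write_extxyz(frame, stream, comment: str = "") -> None:
    """Write one frame as extended XYZ with a Lattice/Properties header."""
    if isinstance(frame, SystemState):
        frame = TrajectoryFrame.from_state(frame)
    n = len(frame.species)
    lat = ("%.17g 0 0 0 %.17g 0 0 0 %.17g"
           % (frame.box[0], frame.box[1], frame.box[2]))
    stream.write("%d\n" % n)
    stream.write('Lattice="%s" Properties=species:S:1:pos:R:3:vel:R:3 '
                 "Step=%d Time=%.17g%s\n"
                 % (lat, frame.step, frame.time,
                    (" " + comment) if comment else ""))
    for i in range(n):
        p = frame.positions[i]
        v = frame.velocities[i]
        stream.write("%s %.17g %.17g %.17g %.17g %.17g %.17g\n"
                     % (SPECIES_LABELS[int(frame.species[i])],
                        p[0], p[1], p[2], v[0], v[1], v[2]))


def read_extxyz(stream):
    """Read all extended-XYZ frames written by :func:`write_extxyz`."""
    frames = []
    lines = stream.read().splitlines()
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        n = int(lines[i])
        header = lines[i + 1]
        if "Lattice=" not in header:
            raise ValueError(f"malformed extxyz header at line {i + 2}")
        lat = header.split('Lattice="')[1].split('"')[0].split()
        box = np.array([float(lat[0]), float(lat[4]), float(lat[8])])
        step = 0
        time = 0.0
        for tok in header.replace('"', " ").split():
            if tok.startswith("Step="):
                step = int(tok[5:])
            elif tok.startswith("Time="):
                time = float(tok[5:])
        species = np.empty(n, dtype=np.int8)
        pos = np.empty((n, 3))
        vel = np.empty((n, 3))
        for k in range(n):
            parts = lines[i + 2 + k].split()
            species[k] = _LABEL_TO_SPECIES[parts[0]]
            pos[k] = [float(x) for x in parts[1:4]]
            vel[k] = [float(x) for x in parts[4:7]]
        frames.append(TrajectoryFrame(step=step, time=time, box=box,
                                      species=species, positions=pos,
                                      velocities=vel))
        i += 2 + n
    return frames


# -- LAMMPS data file (topology export) ----------------------------------

def write_lammps_data(state: SystemState, topology: SystemTopology, stream) -> None:
    """Topology export: Atoms/Bonds/Angles sections, species H=1 T=2 W=3."""
    n = state.n
    nb = topology.bonds.shape[0]
    na = topology.angles.shape[0]
    theta0 = topology.theta0
    uniq_theta = sorted(set(np.round(theta0, 12))) if na else []
    w = stream.write
    w("dpdshear data file\n\n")
    w(f"{n} atoms\n{nb} bonds\n{na} angles\n\n")
    w(f"3 atom types\n{1 if nb else 0} bond types\n{len(uniq_theta)} angle types\n\n")
    for ax, name in enumerate("xyz"):
        w("0 %.17g %slo %shi\n" % (state.box[ax], name, name))
    w("\nAtoms # molecular\n\n")
    per_chain = topology.beads_per_chain
    for i in range(n):
        mol = i // per_chain + 1 if per_chain and i < topology.n_lipid_beads else 0
        p = state.positions[i]
        w("%d %d %d %.17g %.17g %.17g\n"
          % (i + 1, mol, EXPORT_TYPE[int(state.species[i])], p[0], p[1], p[2]))
    if nb:
        w("\nBonds\n\n")
        for b in range(nb):
            w("%d 1 %d %d\n" % (b + 1, topology.bonds[b, 0] + 1,
                                topology.bonds[b, 1] + 1))
    if na:
        w("\nAngles\n\n")
        for a in range(na):
            ty = uniq_theta.index(round(float(theta0[a]), 12)) + 1
            w("%d %d %d %d %d\n" % (a + 1, ty, topology.angles[a, 0] + 1,
                                    topology.angles[a, 1] + 1,
                                    topology.angles[a, 2] + 1))


# -- flat key=value configuration ----------------------------------------

#: defaults reproduce the standard study conditions: bead density 3, time
#: step 0.01 tau, noise sigma = 3 (friction 4.5), bonds k_s = 100 / r_s = 0.7,
#: bending k_theta = 6, box edge 30 r_c, repulsions 50/200.
CONFIG_DEFAULTS = {
    "kind": "random_solution",
    "phi_p": 0.35,
    "L": 30.0,
    "rho": 3.0,
    "n_head": 3,
    "n_tail": 4,
    "n_pores": 3,
    "dt": 0.01,
    "n_steps": 200000,
    "seed": 0,
    "kBT": 1.0,
    "sigma": 3.0,
    "a_like": 50.0,
    "a_unlike": 200.0,
    "k_bond": 100.0,
    "r_bond": 0.7,
    "k_angle": 6.0,
    "lambda": 0.65,
    "sample_every": 100,
    "frame_every": 0,
    "gyration_every": 0,
    "shear": False,
    "W": 5,
    "n_slabs": 20,
    "profile_warmup": 0.25,
}

_RANGES = {
    "phi_p": (0.0, 1.0),
    "L": (1e-9, None),
    "rho": (1e-9, None),
    "dt": (1e-12, None),
    "profile_warmup": (0.0, 1.0),
    "lambda": (0.0, 1.0),
}


def load_config(path_or_stream) -> dict:
    """Parse a flat ``key = value`` file onto the defaults.

    Unknown keys are rejected; values are coerced to the default's type and
    range-checked.  '#' starts a comment.
    """
    if hasattr(path_or_stream, "read"):
        text = path_or_stream.read()
    else:
        with open(path_or_stream) as fh:
            text = fh.read()
    cfg = dict(CONFIG_DEFAULTS)
    for lineno, raw in enumerate(text.splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"line {lineno}: expected key=value, got {raw!r}")
        key, val = (s.strip() for s in line.split("=", 1))
        if key not in cfg:
            raise ValueError(f"line {lineno}: unknown key {key!r}")
        default = CONFIG_DEFAULTS[key]
        try:
            if isinstance(default, bool):
                if val.lower() not in ("true", "false", "0", "1", "yes", "no"):
                    raise ValueError
                parsed = val.lower() in ("true", "1", "yes")
            elif isinstance(default, int):
                parsed = int(val)
            elif isinstance(default, float):
                parsed = float(val)
            else:
                parsed = val
        except ValueError:
            raise ValueError(
                f"line {lineno}: key {key!r} expects "
                f"{type(default).__name__}, got {val!r}") from None
        lo, hi = _RANGES.get(key, (None, None))
        if lo is not None and parsed < lo or hi is not None and parsed > hi:
            raise ValueError(f"line {lineno}: key {key!r} out of range: {parsed}")
        cfg[key] = parsed
    return cfg


def config_hash(cfg: dict) -> str:
    """Stable short hash of a configuration mapping."""
    blob = "\n".join(f"{k}={cfg[k]!r}" for k in sorted(cfg))
    return hashlib.sha256(blob.encode()).hexdigest()[:12]


def provenance_header(cfg: dict | None = None, seed: int | None = None) -> str:
    parts = [f"dpdshear {__version__}"]
    if cfg is not None:
        parts.append(f"config {config_hash(cfg)}")
    if seed is not None:
        parts.append(f"seed {seed}")
    return "# " + " | ".join(parts)


def write_tsv(df, path, cfg: dict | None = None, seed: int | None = None) -> None:
    """Write a DataFrame as TSV with the provenance header line."""
    buf = _io.StringIO()
    df.to_csv(buf, sep="\t", index=False, float_format="%.17g")
    with open(path, "w") as fh:
        fh.write(provenance_header(cfg, seed) + "\n")
        fh.write(buf.getvalue())
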