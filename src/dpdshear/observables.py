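"""Analysis statistics: gyration tensor, shape factor, flow velocity,
energy traces and aggregate clustering.

The squared radius-of-gyration tensor of one chain is the second moment of
its bead positions about the chain mass centre,

    Rg2[a, b] = (1/n) sum_i (r_i[a] - rc[a]) (r_i[b] - rc[b]),

its trace is the squared radius of gyration and its sorted eigenvalues
L1^2 <= L2^2 <= L3^2 give the shape factor

    delta = 1 - 3 (L1^2 L2^2 + L2^2 L3^2 + L1^2 L3^2) / (L1^2 + L2^2 + L3^2)^2,

which is 0 for a sphere and 1 for a rod.  Chains are unwrapped across
periodic images (bond-graph walk, minimum image per bond) before centering.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.spatial import cKDTree

from .state import SystemState
from .topology import TAIL, SystemTopology


# -- gyration ------------------------------------------------------------

def unwrap_chain_positions(chain_pos: np.ndarray, box: np.ndarray,
                           parent: np.ndarray) -> np.ndarray:
    """Unwrap (n_chains, n_beads, 3) positions along the bond-graph walk.

    Bead k is placed at the minimum-image position relative to its already
    placed bonded predecessor ``parent[k]`` (parent[0] = -1 roots the walk).
    """
    box = np.asarray(box, dtype=np.float64)
    out = np.array(chain_pos, dtype=np.float64, copy=True)
    for k in range(1, out.shape[1]):
        p = parent[k]
        d = out[:, k, :] - out[:, p, :]
        d -= box * np.round(d / box)
        out[:, k, :] = out[:, p, :] + d
    return out


@dataclass(frozen=True)
class GyrationResult:
    """Per-chain gyration tensors and their ensemble means."""

    tensors: np.ndarray       # (n_chains, 3, 3)
    eigenvalues: np.ndarray   # (n_chains, 3) ascending
    rg: np.ndarray            # (n_chains,) scalar radius of gyration
    delta: np.ndarray         # (n_chains,) shape factor
    mean_rg: float
    mean_rg_axis: np.ndarray  # (3,) chain-mean of sqrt(Rg2[aa])
    mean_delta: float


def gyration_tensor(chain_pos: np.ndarray, box: np.ndarray | None = None,
                    parent: np.ndarray | None = None) -> GyrationResult:
    """Gyration tensors for chains given as (n_chains, n_beads, 3) positions.

    If ``box`` and ``parent`` are given the chains are unwrapped first.
    Single-bead chains give a zero tensor; an empty input is rejected.
    """
    chain_pos = np.asarray(chain_pos, dtype=np.float64)
    if chain_pos.ndim == 2:
        chain_pos = chain_pos[None, :, :]
    if chain_pos.size == 0 or chain_pos.shape[1] == 0:
        raise ValueError("no beads: gyration tensor undefined")
    if box is not None:
        if parent is None:
            raise ValueError("unwrapping requires the bond-walk parent array")
        chain_pos = unwrap_chain_positions(chain_pos, box, parent)
    centred = chain_pos - chain_pos.mean(axis=1, keepdims=True)
    tensors = np.einsum("cia,cib->cab", centred, centred) / chain_pos.shape[1]
    eig = np.linalg.eigvalsh(tensors)           # ascending
    eig = np.clip(eig, 0.0, None)
    trace = eig.sum(axis=1)
    rg = np.sqrt(trace)
    with np.errstate(invalid="ignore", divide="ignore"):
        cross = (eig[:, 0] * eig[:, 1] + eig[:, 1] * eig[:, 2]
                 + eig[:, 0] * eig[:, 2])
        delta = np.where(trace > 0, 1.0 - 3.0 * cross / trace ** 2, 0.0)
    diag = np.sqrt(np.diagonal(tensors, axis1=1, axis2=2))
    return GyrationResult(
        tensors=tensors, eigenvalues=eig, rg=rg, delta=delta,
        mean_rg=float(rg.mean()), mean_rg_axis=diag.mean(axis=0),
        mean_delta=float(delta.mean()))


def gyration(state: SystemState, topology: SystemTopology) -> GyrationResult:
    """Per-chain gyration statistics of all lipid chains in a state."""
    if topology.n_chains == 0:
        raise ValueError("state contains no chains")
    return gyration_tensor(topology.chain_positions(state.positions),
                           box=state.box, parent=topology.template.parent)


def shape_factor(l1_sq: float, l2_sq: float, l3_sq: float) -> float:
    """Shape factor delta from the three tensor eigenvalues (any order)."""
    eig = np.array([l1_sq, l2_sq, l3_sq], dtype=np.float64)
    if np.any(eig < 0):
        raise ValueError("eigenvalues must be non-negative")
    s = eig.sum()
    if s == 0:
        raise ValueError("all-zero eigenvalues: point chain has no shape")
    cross = eig[0] * eig[1] + eig[1] * eig[2] + eig[0] * eig[2]
    return float(1.0 - 3.0 * cross / s ** 2)


# -- time-series levels --------------------------------------------------

def mean_radius_of_gyration(series: pd.DataFrame, window: float | None = None):
    """Stationary level of the chain-averaged <Rg> trace.

    ``series`` is an observables table with ``time`` and ``rg_mean`` (and
    optionally ``rg_xx``/``rg_yy``/``rg_zz``) columns.  The level is the
    least-squares constant fit (the mean) over the final ``window`` time
    units (default: the last half).  Returns a dict of levels.
    """
    df = series.dropna(subset=["rg_mean"])
    if not len(df):
        raise ValueError("empty window: no gyration samples")
    t = df["time"].to_numpy()
    t0 = t[-1] - window if window is not None else t[0] + 0.5 * (t[-1] - t[0])
    sel = df[t >= t0] if len(df) > 1 else df
    out = {"rg_mean": float(sel["rg_mean"].mean())}
    for col in ("rg_xx", "rg_yy", "rg_zz", "delta_mean"):
        if col in sel:
            out[col] = float(sel[col].mean())
    return out


def mean_flow_velocity_frame(state: SystemState, n_slabs: int = 20) -> float:
    """Sign-folded mean flow speed of one frame.

    v_x is averaged within each z-slab (cancelling thermal motion), then the
    slab means are folded by |.| and averaged: the two halves of the box
    stream in opposite x-directions under the swap protocol, so a raw mean
    would vanish while folding makes the counter-flows add.  For an ideal
    sawtooth profile of branch slope gamma_dot this equals
    gamma_dot * L_z / 8; at shear-free equilibrium it is ~0 within slab
    sampling noise.
    """
    from .shear import assign_slabs
    slabs = assign_slabs(state, n_slabs)
    sums = np.zeros(n_slabs)
    counts = np.zeros(n_slabs)
    np.add.at(sums, slabs, state.velocities[:, 0])
    np.add.at(counts, slabs, 1)
    occupied = counts > 0
    return float(np.mean(np.abs(sums[occupied] / counts[occupied])))


def mean_flow_velocity(series: pd.DataFrame, tail_fraction: float = 1 / 3):
    """<v_x>(t) series and its saturation level.

    The saturation is the mean of the folded flow speed over the final
    ``tail_fraction`` of the window.
    """
    if not len(series):
        raise ValueError("empty window")
    v = series["vx_mean_abs"].to_numpy()
    n_tail = max(1, int(np.ceil(tail_fraction * len(v))))
    return v, float(v[-n_tail:].mean())


@dataclass(frozen=True)
class PlateauResult:
    """Stationary-level detection on an energy (or any) trace."""

    mean: float          # plateau level
    onset_time: float    # first time the sliding slope stays small
    onset_index: int


def detect_plateau(time: np.ndarray, values: np.ndarray,
                   window: float = 200.0, slope_tol: float = 1e-4
                   ) -> PlateauResult:
    """Find the stationary stage of a relaxation trace.

    A sliding least-squares slope over ``window`` time units is compared to
    ``slope_tol`` (units of value per tau); the plateau starts at the first
    window whose slope magnitude stays below tolerance, and the level is
    the mean from onset to the end.
    """
    time = np.asarray(time, dtype=np.float64)
    values = np.asarray(values, dtype=np.float64)
    if time.size < 2 or time[-1] - time[0] < window:
        raise ValueError("trace shorter than the detection window")
    dt = np.median(np.diff(time))
    k = max(2, int(round(window / dt)))
    onset = None
    for start in range(0, time.size - k + 1):
        seg_t = time[start:start + k]
        seg_v = values[start:start + k]
        slope = np.polyfit(seg_t - seg_t[0], seg_v, 1)[0]
        if abs(slope) < slope_tol:
            onset = start
            break
    if onset is None:
        raise ValueError("no plateau found below the slope tolerance")
    return PlateauResult(mean=float(values[onset:].mean()),
                         onset_time=float(time[onset]), onset_index=onset)


def energy_trace(series: pd.DataFrame, window: float = 200.0,
                 slope_tol: float = 1e-4) -> dict:
    """Per-bead energy components plus the total-energy plateau.

    Returns the components table (already per bead) and the plateau of
    ``e_total``.
    """
    plateau = detect_plateau(series["time"].to_numpy(),
                             series["e_total"].to_numpy(),
                             window=window, slope_tol=slope_tol)
    return {"series": series[["step", "time", "e_pair", "e_bond", "e_angle",
                              "e_kinetic", "e_total"]],
            "plateau": plateau}


# -- aggregates ----------------------------------------------------------

def cluster_aggregates(state: SystemState, cutoff: float = 1.0):
    """Connected components of the tail-bead contact graph.

    Two hydrophobic (T) beads are in contact when their minimum-image
    distance is below ``cutoff``.  Returns (labels over T beads, n_clusters,
    T-bead indices).
    """
    t_idx = np.flatnonzero(state.species == TAIL)
    if t_idx.size == 0:
        return np.empty(0, dtype=np.int64), 0, t_idx
    pos = state.positions[t_idx]
    tree = cKDTree(np.mod(pos, state.box), boxsize=state.box)
    pairs = tree.query_pairs(cutoff, output_type="ndarray")
    m = t_idx.size
    adj = sparse.coo_matrix(
        (np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(m, m))
    n_comp, labels = sparse.csgraph.connected_components(adj, directed=False)
    return labels, int(n_comp), t_idx
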