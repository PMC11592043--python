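"""Trajectory detection (Floyd–Warshall) and per-cell pseudo-time.

All-pairs shortest paths on the population graph are computed with the
Floyd–Warshall recurrence

    H_{s,q}^{(ν+1)} = min( H_{s,q}^{(ν)}, H_{s,o}^{(ν)} + H_{o,q}^{(ν)} ),

which tolerates negative edge weights (a negative *cycle* is an error).
Trajectories are source→sink shortest paths chosen greedily to cover the
populations; pseudo-time then places each population at its integer path
position t_s and orders cells *within* a population by projecting them onto
the population's velocity line W(t) = X*_s + v_s (t − t_s):

    x̂ = X*_s + ((x − X*_s)·v_s / ‖v_s‖²) v_s,   t_si = t_s + δ,

with δ rescaled to (−0.45, +0.45) inside each population so population
order stays authoritative, and a final min–max normalization to [0, 1].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .cellpop import CellPopulation
from .errors import TrajectoryError
from .graph import PopulationGraph

log = logging.getLogger(__name__)


def floyd_warshall(g: PopulationGraph) -> tuple[np.ndarray, np.ndarray]:
    """All-pairs shortest paths; returns (dist, next_hop) over node indices.

    ``dist[i, j]`` is the minimal path cost from ``g.pop_ids[i]`` to
    ``g.pop_ids[j]`` (∞ if unreachable, 0 on the diagonal); ``next_hop``
    reconstructs one optimal path per pair (−1 where undefined). Intermediate
    nodes are scanned in ascending pop_id with strict improvement only, so
    ties resolve deterministically toward smaller intermediates.
    """
    ids = list(g.pop_ids)
    index = {p: i for i, p in enumerate(ids)}
    G = len(ids)
    dist = np.full((G, G), np.inf)
    np.fill_diagonal(dist, 0.0)
    nxt = np.full((G, G), -1, dtype=int)
    nxt[np.diag_indices(G)] = np.arange(G)
    for e in g.edges:
        s, q = index[e.source], index[e.target]
        if e.weight < dist[s, q]:
            dist[s, q] = e.weight
            nxt[s, q] = q
    for o in np.argsort(ids, kind="stable"):  # ascending pop_id
        alt = dist[:, o][:, None] + dist[o, :][None, :]
        better = alt < dist
        if better.any():
            dist = np.where(better, alt, dist)
            rows = np.nonzero(better.any(axis=1))[0]
            for s in rows:
                nxt[s, better[s]] = nxt[s, o]
    if np.any(np.diag(dist) < 0):
        raise TrajectoryError("negative cycle detected in population graph")
    return dist, nxt


def reconstruct_path(g: PopulationGraph, nxt: np.ndarray, source: int, target: int) -> list[int]:
    """Pop-id sequence of one shortest path source→target (inclusive)."""
    ids = list(g.pop_ids)
    index = {p: i for i, p in enumerate(ids)}
    s, q = index[source], index[target]
    if nxt[s, q] < 0:
        raise TrajectoryError(f"no path from {source} to {target}")
    path = [s]
    guard = 0
    while path[-1] != q:
        path.append(int(nxt[path[-1], q]))
        guard += 1
        if guard > len(ids):
            raise TrajectoryError("path reconstruction did not terminate")
    return [ids[i] for i in path]


@dataclass
class Trajectory:
    """An ordered population path plus per-cell pseudo-time."""

    path_id: int
    pop_sequence: list[int]              # pop_ids along graph edges
    assigned_pops: list[int] = field(default_factory=list)  # pops timed by this path
    pop_times: dict[int, float] = field(default_factory=dict)  # pop_id -> t_s
    cell_times_raw: dict[int, float] = field(default_factory=dict)   # cell idx -> t_si
    cell_times: dict[int, float] = field(default_factory=dict)       # normalized [0,1]
    mean_edge_weight: float = float("nan")


def detect_trajectories(
    g: PopulationGraph,
    dist: np.ndarray,
    next_hop: np.ndarray,
    max_paths: int = 20,
    coverage_target: float = 0.95,
) -> list[Trajectory]:
    """Greedy coverage selection among source→sink shortest paths.

    Sources are in-degree-0 nodes (or, failing that, the nodes of minimal
    in-degree); sinks are out-degree-0 nodes (or the targets of maximal
    finite shortest-path distance). Paths are picked by most not-yet-covered
    populations, ties broken by lower mean edge weight, until
    ``coverage_target`` of the coverable populations are covered or
    ``max_paths`` is reached. Each population is *assigned* to the first
    selected path that covers it.
    """
    if g.n_nodes == 0:
        raise TrajectoryError("empty population graph")
    ids = list(g.pop_ids)
    index = {p: i for i, p in enumerate(ids)}
    indeg = g.in_degrees()
    outdeg = g.out_degrees()
    sources = [p for p in ids if indeg[p] == 0]
    if not sources:
        lo = min(indeg.values())
        sources = [p for p in ids if indeg[p] == lo]
    sinks = [p for p in ids if outdeg[p] == 0]
    if not sinks:
        finite = np.where(np.isfinite(dist), dist, -np.inf)
        far = finite.max(axis=0)
        sinks = [ids[i] for i in np.nonzero(far == far.max())[0]]

    weight_of = {(e.source, e.target): e.weight for e in g.edges}
    candidates: list[Trajectory] = []
    for s in sources:
        for q in sinks:
            if s == q or not np.isfinite(dist[index[s], index[q]]):
                continue
            seq = reconstruct_path(g, next_hop, s, q)
            w = [weight_of[(a, b)] for a, b in zip(seq, seq[1:])]
            candidates.append(
                Trajectory(
                    path_id=-1, pop_sequence=seq,
                    mean_edge_weight=float(np.mean(w)) if w else float("inf"),
                )
            )
    if not candidates:
        raise TrajectoryError("no source-to-sink path exists in the graph")

    coverable = set()
    for c in candidates:
        coverable.update(c.pop_sequence)
    covered: set[int] = set()
    selected: list[Trajectory] = []
    remaining = list(candidates)
    while len(selected) < max_paths and len(covered) < coverage_target * len(coverable):
        best = None
        best_key = None
        for c in remaining:
            new = len(set(c.pop_sequence) - covered)
            key = (-new, c.mean_edge_weight, c.pop_sequence[0], c.pop_sequence[-1])
            if best is None or key < best_key:
                best, best_key = c, key
        if best is None or -best_key[0] == 0:
            break
        best.path_id = len(selected)
        best.assigned_pops = [p for p in best.pop_sequence if p not in covered]
        covered.update(best.pop_sequence)
        remaining.remove(best)
        selected.append(best)
    if not selected:
        raise TrajectoryError("greedy selection produced no trajectory")
    return selected


def project_cell(x: np.ndarray, cp: CellPopulation) -> tuple[np.ndarray, float]:
    """Orthogonal projection of a cell onto its population's velocity line.

    Returns (x̂, δ) with x̂ = X*_s + δ·v_s and δ = (x − X*_s)·v_s / ‖v_s‖²,
    so that the cell's raw time is t_s + δ.
    """
    if cp.velocity is None or not np.any(cp.velocity):
        raise TrajectoryError(f"CP {cp.pop_id} has zero velocity")
    v = cp.velocity
    delta = float((np.asarray(x, float) - cp.centroid) @ v / (v @ v))
    return cp.centroid + delta * v, delta


def assign_pseudotime(
    traj: Trajectory,
    pops: list[CellPopulation],
    X: np.ndarray,
    rescale_bound: float = 0.45,
) -> Trajectory:
    """Fill per-cell raw and normalized pseudo-times for one trajectory.

    Populations take integer times t_s = 0, 1, 2, … by path position; member
    cells of each population assigned to this path are offset by their
    velocity-line projection δ, rescaled within the population to
    ±``rescale_bound`` (dividing by max|δ|; 0 when all δ vanish), then the
    path's times are min–max normalized to [0, 1].
    """
    by_id = {p.pop_id: p for p in pops}
    traj.pop_times = {p: float(t) for t, p in enumerate(traj.pop_sequence)}
    assigned = traj.assigned_pops if traj.assigned_pops else list(traj.pop_sequence)
    raw: dict[int, float] = {}
    for pid in assigned:
        cp = by_id[pid]
        t_s = traj.pop_times[pid]
        deltas = np.array([project_cell(X[i], cp)[1] for i in cp.members])
        dmax = np.max(np.abs(deltas))
        scaled = deltas / dmax * rescale_bound if dmax > 0 else np.zeros_like(deltas)
        for i, d in zip(cp.members, scaled):
            raw[int(i)] = t_s + float(d)
    traj.cell_times_raw = raw
    values = np.array(list(raw.values()))
    lo, hi = values.min(), values.max()
    if hi > lo:
        traj.cell_times = {i: (t - lo) / (hi - lo) for i, t in raw.items()}
    else:
        if len(raw) > 1:
            log.warning("path %d has a single distinct raw time", traj.path_id)
        traj.cell_times = {i: 0.0 for i in raw}
    return traj
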