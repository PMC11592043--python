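"""Directed weighted k-nearest-neighbor graph over cell populations.

Each CP s is linked to its k nearest CPs (Euclidean centroid distance).
An edge s→q carries two dissimilarities:

    l_α(s,q) = 1 − cos α,  cos α = (X*_q − X*_s)ᵀ v_s / (‖X*_q − X*_s‖ ‖v_s‖)
    l_d(s,q) = d_{s,q} / d_max                    (d_max global over candidates)

and the weight combines them nonlinearly with a scaling factor λ > 1 and a
distance factor β > 0:

    e_{s,q} = λ^{l_α(s,q) + β·l_d(s,q)} / λ.

An edge pointing exactly where the source's velocity points has l_α = 0 and
is cheapest; one pointing against it has l_α = 2. With ``prune_backward``
edges at more than 90° to the source velocity (l_α > 1) are dropped, so
trajectories can only move with the flow.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .cellpop import CellPopulation
from .errors import GraphError

log = logging.getLogger(__name__)


@dataclass
class Edge:
    source: int   # pop_id
    target: int   # pop_id
    l_alpha: float
    l_d: float
    weight: float


@dataclass
class PopulationGraph:
    """Directed weighted graph on cell populations."""

    pop_ids: list[int]
    edges: list[Edge]
    k: int
    lam: float
    beta: float

    @property
    def n_nodes(self) -> int:
        return len(self.pop_ids)

    def out_degree(self, pop_id: int) -> int:
        return sum(1 for e in self.edges if e.source == pop_id)

    def in_degrees(self) -> dict[int, int]:
        deg = {p: 0 for p in self.pop_ids}
        for e in self.edges:
            deg[e.target] += 1
        return deg

    def out_degrees(self) -> dict[int, int]:
        deg = {p: 0 for p in self.pop_ids}
        for e in self.edges:
            deg[e.source] += 1
        return deg

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(e.source, e.target, e.l_alpha, e.l_d, e.weight) for e in self.edges],
            columns=["source", "target", "l_alpha", "l_d", "weight"],
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, k: int = 0, lam: float = np.nan,
                       beta: float = np.nan) -> "PopulationGraph":
        edges = [
            Edge(int(r.source), int(r.target), float(r.l_alpha), float(r.l_d),
                 float(r.weight))
            for r in df.itertuples()
        ]
        pops = sorted({e.source for e in edges} | {e.target for e in edges})
        return cls(pop_ids=pops, edges=edges, k=k, lam=lam, beta=beta)

    def to_networkx(self):
        import networkx as nx

        g = nx.DiGraph()
        g.add_nodes_from(self.pop_ids)
        for e in self.edges:
            g.add_edge(e.source, e.target, l_alpha=e.l_alpha, l_d=e.l_d,
                       weight=e.weight)
        return g


def expression_difference(cp_s: CellPopulation, cp_q: CellPopulation) -> float:
    """l_α(s,q) = 1 − cos α with the displacement taken toward the target.

    cos α compares the centroid displacement X*_q − X*_s with the source
    population's velocity v_s; a displacement along v_s gives l_α = 0,
    against it l_α = 2.
    """
    if cp_s.velocity is None:
        raise GraphError(f"CP {cp_s.pop_id} has no velocity")
    disp = cp_q.centroid - cp_s.centroid
    dn = float(np.linalg.norm(disp))
    vn = float(np.linalg.norm(cp_s.velocity))
    if dn == 0.0:
        raise GraphError(
            f"CPs {cp_s.pop_id} and {cp_q.pop_id} have coincident centroids"
        )
    if vn == 0.0:
        raise GraphError(f"CP {cp_s.pop_id} has zero velocity")
    cos_a = float(disp @ cp_s.velocity) / (dn * vn)
    cos_a = min(1.0, max(-1.0, cos_a))
    return 1.0 - cos_a


def build_knn_graph(
    pops: list[CellPopulation],
    k: int = 10,
    lam: float = 3.0,
    beta: float = 1.0,
    prune_backward: bool = True,
) -> PopulationGraph:
    """Build the directed weighted kNN graph on CP centroids.

    d_max normalizing l_d is the maximum distance over all retained
    candidate kNN edges (global, so l_d is comparable across the graph).
    """
    if len(pops) < 2:
        raise GraphError("need at least 2 cell populations")
    if k < 1:
        raise GraphError("k must be >= 1")
    if lam <= 1:
        raise GraphError("lambda must be > 1")
    if beta <= 0:
        raise GraphError("beta must be > 0")
    if k >= len(pops):
        log.warning("k=%d >= number of CPs; clamped to %d", k, len(pops) - 1)
        k = len(pops) - 1

    centroids = np.vstack([p.centroid for p in pops])
    dists = cdist(centroids, centroids)
    np.fill_diagonal(dists, np.inf)

    candidates: list[tuple[int, int, float]] = []  # (s_idx, q_idx, d)
    for s in range(len(pops)):
        order = np.argsort(dists[s], kind="stable")[:k]
        for q in order:
            d = dists[s, q]
            if not np.isfinite(d):
                continue
            if d == 0.0:
                log.warning(
                    "skipping edge %d->%d with coincident centroids",
                    pops[s].pop_id, pops[int(q)].pop_id,
                )
                continue
            candidates.append((s, int(q), float(d)))
    if not candidates:
        raise GraphError("no usable candidate edges (all centroids coincide?)")
    d_max = max(d for _, _, d in candidates)

    edges: list[Edge] = []
    for s, q, d in candidates:
        try:
            l_alpha = expression_difference(pops[s], pops[q])
        except GraphError:
            log.warning(
                "CP %d has zero velocity; using neutral l_alpha=1", pops[s].pop_id
            )
            l_alpha = 1.0
        l_d = d / d_max
        weight = lam ** (l_alpha + beta * l_d) / lam
        if prune_backward and l_alpha > 1.0:
            continue
        edges.append(Edge(pops[s].pop_id, pops[q].pop_id, l_alpha, l_d, weight))
    return PopulationGraph(
        pop_ids=[p.pop_id for p in pops], edges=edges, k=k, lam=lam, beta=beta
    )
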