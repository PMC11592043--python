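"""Refinement of GMM clusters into cell populations (CPs).

A cell population is a small sub-cluster — analogous to a metacell — that
keeps cell-specific information a whole cluster would average away. Each
GMM cluster k is split by seeded k-means into

    s_k = max(1, round(|C_k| / target_pop_size))

populations. Population ids are assigned deterministically: sorted by
parent cluster, then by smallest member cell index.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans

from .dataset import ExpressionDataset
from .errors import DataError
from .gmm import MixtureModel

log = logging.getLogger(__name__)


@dataclass
class CellPopulation:
    """A refined sub-cluster: members, centroid and (later) smoothed velocity."""

    pop_id: int
    parent_cluster: int
    members: np.ndarray              # sorted cell indices, non-empty
    centroid: np.ndarray             # (n,) arithmetic mean of member expression
    velocity: np.ndarray | None = None  # (n,) filled by the GPR stage

    @property
    def size(self) -> int:
        return len(self.members)


def refine_clusters(
    ds_or_X,
    model: MixtureModel | np.ndarray,
    target_pop_size: int = 20,
    seed: int = 0,
) -> list[CellPopulation]:
    """Split each GMM cluster into cell populations by seeded k-means.

    ``model`` may be a fitted :class:`MixtureModel` or a plain assignment
    vector. Deterministic given (assignments, target_pop_size, seed).
    """
    X = ds_or_X.spliced if isinstance(ds_or_X, ExpressionDataset) else np.asarray(ds_or_X, float)
    assignments = model.assignments if isinstance(model, MixtureModel) else np.asarray(model)
    if target_pop_size < 1:
        raise DataError("target_pop_size must be >= 1")
    if len(assignments) != X.shape[0]:
        raise DataError("assignment vector length does not match cell count")

    raw: list[tuple[int, np.ndarray]] = []  # (parent_cluster, member idx)
    for k in np.unique(assignments):
        idx = np.flatnonzero(assignments == k)
        if idx.size == 0:  # pragma: no cover - unique() never yields empties
            log.warning("cluster %d is empty; skipped", k)
            continue
        s_k = max(1, int(np.floor(idx.size / target_pop_size + 0.5)))
        s_k = min(s_k, idx.size)
        if s_k == 1:
            raw.append((int(k), idx))
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # duplicate points may yield < s_k centers
            km = KMeans(n_clusters=s_k, random_state=seed, n_init=10).fit(X[idx])
        labels = np.unique(km.labels_)
        if len(labels) < s_k:
            # too few distinct points for k-means; split evenly instead
            for part in np.array_split(idx, s_k):
                raw.append((int(k), part))
        else:
            for lbl in labels:
                raw.append((int(k), idx[km.labels_ == lbl]))

    raw.sort(key=lambda t: (t[0], int(t[1].min())))
    pops = [
        CellPopulation(
            pop_id=i,
            parent_cluster=parent,
            members=np.sort(members),
            centroid=X[members].mean(axis=0),
        )
        for i, (parent, members) in enumerate(raw)
    ]
    total = sum(p.size for p in pops)
    if total != X.shape[0]:  # pragma: no cover - partition is structural
        raise DataError("cell populations do not partition the cells")
    return pops
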