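import numpy as np
import pytest

from poptraj import ExpressionDataset
from poptraj.cellpop import CellPopulation


@pytest.fixture
def tiny_dataset():
    """3 cells x 2 genes with hand-written values."""
    return ExpressionDataset(
        spliced=np.array([[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]]),
        unspliced=np.array([[0.5, 1.0], [1.5, 2.0], [2.5, 3.0]]),
        velocity=np.array([[0.1, -0.2], [0.3, 0.4], [-0.5, 0.6]]),
        cell_ids=["c1", "c2", "c3"],
        gene_ids=["g1", "g2"],
        truth_time=np.array([0.0, 0.5, 1.0]),
        truth_branch=np.array(["a", "a", "b"]),
    )


def make_dataset(X, V=None, U=None, truth_time=None):
    """Wrap plain matrices into an ExpressionDataset for unit tests."""
    X = np.atleast_2d(np.asarray(X, float))
    m, n = X.shape
    return ExpressionDataset(
        spliced=X,
        unspliced=U if U is not None else np.zeros_like(X),
        velocity=V if V is not None else np.zeros_like(X),
        cell_ids=[f"c{i}" for i in range(m)],
        gene_ids=[f"g{j}" for j in range(n)],
        truth_time=truth_time,
    )


def chain_populations(centroids, velocities, members_per_pop):
    """Build CellPopulations with explicit centroids/velocities/members."""
    pops = []
    for pid, (c, v, mem) in enumerate(zip(centroids, velocities, members_per_pop)):
        pops.append(
            CellPopulation(
                pop_id=pid,
                parent_cluster=0,
                members=np.asarray(mem, dtype=int),
                centroid=np.asarray(c, dtype=float),
                velocity=None if v is None else np.asarray(v, dtype=float),
            )
        )
    return pops
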