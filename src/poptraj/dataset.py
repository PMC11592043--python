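"""Input/output and preprocessing for velocity-annotated expression data.

The working unit is an :class:`ExpressionDataset`: three aligned cells×genes
matrices (spliced, unspliced, RNA velocity) plus identifiers and optional
ground truth. Velocity is an *input* here — it is expected to come from an
upstream estimator such as scVelo or velocyto; this package never estimates it.

Three on-disk dialects are supported:

``mtx``
    a directory with ``spliced.mtx`` / ``unspliced.mtx`` / ``velocity.mtx``
    (Matrix Market, dense or coordinate) plus ``cells.tsv`` and ``genes.tsv``
    two-column id files and an optional ``truth.csv``;
``delimited``
    the same layout with ``.csv`` matrices carrying cell-id row index and
    gene-id header;
``h5ad``
    an AnnData container whose layers are named ``"spliced"``,
    ``"unspliced"`` and ``"velocity"``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .errors import DataError, DimensionMismatchError, MissingVelocityError

LAYERS = ("spliced", "unspliced", "velocity")

_TRUTH_FILE = "truth.csv"


@dataclass
class ExpressionDataset:
    """Aligned spliced / unspliced / velocity matrices with identifiers.

    All three matrices are dense float arrays of shape (m cells, n genes)
    with identical row/column ordering. ``truth_time`` (values in [0, 1])
    and ``truth_branch`` are optional per-cell ground truth used only for
    evaluation of inferred pseudo-time.
    """

    spliced: np.ndarray
    unspliced: np.ndarray
    velocity: np.ndarray
    cell_ids: list[str]
    gene_ids: list[str]
    truth_time: np.ndarray | None = None
    truth_branch: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.spliced = _as_dense(self.spliced)
        self.unspliced = _as_dense(self.unspliced)
        self.velocity = _as_dense(self.velocity)
        self.cell_ids = [str(c) for c in self.cell_ids]
        self.gene_ids = [str(g) for g in self.gene_ids]
        m, n = self.spliced.shape
        for name in ("unspliced", "velocity"):
            layer = getattr(self, name)
            if layer.shape != (m, n):
                raise DimensionMismatchError(
                    f"layer '{name}' has shape {layer.shape}, expected {(m, n)} "
                    f"to match 'spliced'"
                )
        if len(self.cell_ids) != m:
            raise DimensionMismatchError(
                f"{len(self.cell_ids)} cell ids for {m} matrix rows"
            )
        if len(self.gene_ids) != n:
            raise DimensionMismatchError(
                f"{len(self.gene_ids)} gene ids for {n} matrix columns"
            )
        if len(set(self.cell_ids)) != m:
            raise DataError("duplicate cell ids")
        if len(set(self.gene_ids)) != n:
            raise DataError("duplicate gene ids")
        if self.truth_time is not None:
            self.truth_time = np.asarray(self.truth_time, dtype=float)
            if self.truth_time.shape != (m,):
                raise DimensionMismatchError("truth_time length must equal cell count")
            if self.truth_time.min() < 0 or self.truth_time.max() > 1:
                raise DataError("truth_time values must lie in [0, 1]")
        if self.truth_branch is not None:
            self.truth_branch = np.asarray(self.truth_branch, dtype=object)
            if self.truth_branch.shape != (m,):
                raise DimensionMismatchError("truth_branch length must equal cell count")

    @property
    def n_cells(self) -> int:
        return self.spliced.shape[0]

    @property
    def n_genes(self) -> int:
        return self.spliced.shape[1]

    def subset_genes(self, mask_or_idx) -> "ExpressionDataset":
        """Return a copy restricted to the given genes (all layers alike)."""
        idx = np.asarray(mask_or_idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return replace(
            self,
            spliced=self.spliced[:, idx].copy(),
            unspliced=self.unspliced[:, idx].copy(),
            velocity=self.velocity[:, idx].copy(),
            gene_ids=[self.gene_ids[j] for j in idx],
        )


def _as_dense(x) -> np.ndarray:
    if scipy.sparse.issparse(x):
        x = x.toarray()
    return np.asarray(x, dtype=float)


def _infer_format(path: Path) -> str:
    if path.suffix in {".h5ad", ".h5"}:
        return "h5ad"
    if (path / "spliced.mtx").exists():
        return "mtx"
    if (path / "spliced.csv").exists():
        return "delimited"
    raise DataError(f"cannot infer dataset format at {path}")


def load_dataset(path, format: str | None = None) -> ExpressionDataset:
    """Load an :class:`ExpressionDataset` from disk.

    Parameters
    ----------
    path
        File (``h5ad``) or directory (``mtx`` / ``delimited``) location.
    format
        One of ``"mtx"``, ``"delimited"``, ``"h5ad"``; inferred when omitted.
    """
    path = Path(path)
    if not path.exists():
        raise DataError(f"no such path: {path}")
    fmt = format or _infer_format(path)
    if fmt == "h5ad":
        return _load_h5ad(path)
    if fmt in ("mtx", "delimited"):
        return _load_triplet(path, fmt)
    raise DataError(f"unknown format '{fmt}'")


def _load_h5ad(path: Path) -> ExpressionDataset:
    import anndata as ad

    adata = ad.read_h5ad(path)
    layers = {}
    for name in LAYERS:
        if name in adata.layers:
            layers[name] = _as_dense(adata.layers[name])
        elif name == "spliced":
            layers[name] = _as_dense(adata.X)
        elif name == "velocity":
            raise MissingVelocityError(
                "container has no 'velocity' layer; RNA velocity must be computed "
                "upstream (e.g. with scVelo or velocyto) before trajectory inference"
            )
        else:
            raise DataError(f"container has no '{name}' layer")
    truth_time = (
        adata.obs["truth_time"].to_numpy() if "truth_time" in adata.obs else None
    )
    truth_branch = (
        adata.obs["truth_branch"].to_numpy() if "truth_branch" in adata.obs else None
    )
    return ExpressionDataset(
        spliced=layers["spliced"],
        unspliced=layers["unspliced"],
        velocity=layers["velocity"],
        cell_ids=list(adata.obs_names),
        gene_ids=list(adata.var_names),
        truth_time=truth_time,
        truth_branch=truth_branch,
    )


def _load_triplet(path: Path, fmt: str) -> ExpressionDataset:
    ext = "mtx" if fmt == "mtx" else "csv"
    mats: dict[str, np.ndarray] = {}
    cell_ids = gene_ids = None
    if fmt == "mtx":
        cells = pd.read_csv(path / "cells.tsv", sep="\t", header=None)
        genes = pd.read_csv(path / "genes.tsv", sep="\t", header=None)
        cell_ids = list(cells.iloc[:, -1].astype(str))
        gene_ids = list(genes.iloc[:, -1].astype(str))
    for name in LAYERS:
        f = path / f"{name}.{ext}"
        if not f.exists():
            if name == "velocity":
                raise MissingVelocityError(
                    f"missing {f.name}: RNA velocity must be computed upstream "
                    "(e.g. with scVelo or velocyto) and supplied as a third matrix"
                )
            raise DataError(f"missing layer file {f}")
        if fmt == "mtx":
            mats[name] = _as_dense(scipy.io.mmread(f))
        else:
            df = pd.read_csv(f, index_col=0, float_precision="round_trip")
            if cell_ids is None:
                cell_ids = list(df.index.astype(str))
                gene_ids = list(df.columns.astype(str))
            mats[name] = df.to_numpy(dtype=float)
    truth_time = truth_branch = None
    tf = path / _TRUTH_FILE
    if tf.exists():
        tr = (
            pd.read_csv(tf, float_precision="round_trip")
            .set_index("cell_id")
            .loc[cell_ids]
        )
        if "time" in tr:
            truth_time = tr["time"].to_numpy(dtype=float)
        if "branch" in tr:
            truth_branch = tr["branch"].to_numpy()
    return ExpressionDataset(
        spliced=mats["spliced"],
        unspliced=mats["unspliced"],
        velocity=mats["velocity"],
        cell_ids=cell_ids,
        gene_ids=gene_ids,
        truth_time=truth_time,
        truth_branch=truth_branch,
    )


def write_dataset(ds: ExpressionDataset, path, format: str = "delimited") -> None:
    """Write a dataset in one of the supported dialects (lossless round trip)."""
    path = Path(path)
    if format == "h5ad":
        import anndata as ad

        adata = ad.AnnData(
            X=ds.spliced.copy(),
            layers={name: getattr(ds, name).copy() for name in LAYERS},
        )
        adata.obs_names = ds.cell_ids
        adata.var_names = ds.gene_ids
        if ds.truth_time is not None:
            adata.obs["truth_time"] = ds.truth_time
        if ds.truth_branch is not None:
            adata.obs["truth_branch"] = pd.Categorical(ds.truth_branch)
        path.parent.mkdir(parents=True, exist_ok=True)
        adata.write_h5ad(path)
        return
    path.mkdir(parents=True, exist_ok=True)
    if format == "mtx":
        for name in LAYERS:
            scipy.io.mmwrite(path / f"{name}.mtx", getattr(ds, name), precision=17)
        pd.DataFrame({0: range(ds.n_cells), 1: ds.cell_ids}).to_csv(
            path / "cells.tsv", sep="\t", header=False, index=False
        )
        pd.DataFrame({0: range(ds.n_genes), 1: ds.gene_ids}).to_csv(
            path / "genes.tsv", sep="\t", header=False, index=False
        )
    elif format == "delimited":
        for name in LAYERS:
            pd.DataFrame(
                getattr(ds, name), index=ds.cell_ids, columns=ds.gene_ids
            ).to_csv(path / f"{name}.csv", float_format="%.17g")
    else:
        raise DataError(f"unknown format '{format}'")
    if ds.truth_time is not None or ds.truth_branch is not None:
        truth = pd.DataFrame({"cell_id": ds.cell_ids})
        if ds.truth_time is not None:
            truth["time"] = ds.truth_time
        if ds.truth_branch is not None:
            truth["branch"] = ds.truth_branch
        truth.to_csv(path / _TRUTH_FILE, index=False, float_format="%.17g")


def preprocess(
    ds: ExpressionDataset,
    min_counts: int = 20,
    n_top_genes: int = 2000,
    log1p: bool = True,
    normalize: bool = True,
) -> ExpressionDataset:
    """Basic gene filtering, library-size normalization and log transform.

    Mirrors the usual scVelo-style protocol for raw spliced/unspliced counts:
    genes whose total spliced count falls below ``min_counts`` are dropped
    from all three layers; spliced and unspliced are scaled per cell to the
    median pre-normalization total; ``log1p`` applies log(1+x) to spliced and
    unspliced. The velocity layer is only ever subset, never rescaled or
    transformed — it is taken to be on the working expression scale already.
    Finally the ``n_top_genes`` highest-dispersion genes (variance/mean of
    normalized spliced) are kept, applied identically to all layers;
    ``n_top_genes`` is clamped to the number of genes present.
    """
    if min_counts < 0:
        raise DataError("min_counts must be >= 0")
    totals_per_gene = ds.spliced.sum(axis=0)
    keep = totals_per_gene >= min_counts
    if not keep.any():
        raise DataError(
            f"all {ds.n_genes} genes filtered out at min_counts={min_counts}"
        )
    out = ds.subset_genes(keep) if not keep.all() else ds
    spliced, unspliced = out.spliced, out.unspliced
    if normalize:
        cell_totals = spliced.sum(axis=1)
        if (cell_totals <= 0).any():
            raise DataError("cells with non-positive spliced total cannot be normalized")
        median_total = float(np.median(cell_totals))
        spliced = spliced * (median_total / cell_totals)[:, None]
        u_totals = unspliced.sum(axis=1)
        if (u_totals > 0).any():
            u_median = np.median(u_totals[u_totals > 0])
            with np.errstate(divide="ignore", invalid="ignore"):
                u_scale = np.where(u_totals > 0, u_median / u_totals, 1.0)
            unspliced = unspliced * u_scale[:, None]
    if log1p:
        spliced = np.log1p(spliced)
        unspliced = np.log1p(unspliced)
    out = replace(out, spliced=spliced, unspliced=unspliced)
    n_top = min(int(n_top_genes), out.n_genes)
    if n_top < out.n_genes:
        mean = out.spliced.mean(axis=0)
        var = out.spliced.var(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            dispersion = np.where(mean > 0, var / mean, 0.0)
        top = np.sort(np.argsort(dispersion)[::-1][:n_top])  # keep gene order
        out = out.subset_genes(top)
    return out
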