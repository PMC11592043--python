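"""Gaussian-process regression of RNA velocity onto cell populations.

Cell-level velocities are noisy; the population works with a smoothed
velocity evaluated at each CP centroid. With training expression X, training
velocities V and query centroids X*, the GP posterior mean and variance are

    μ*       = μ_V + K(X*, X) (K(X, X) + σ²I)⁻¹ (V − μ_V)
    diag Σ*  = diag[ K(X*, X*) + σ²I − K(X*, X)(K(X,X)+σ²I)⁻¹K(X, X*) ]

under an RBF (Gaussian) kernel k(a, b) = σ_RBF² exp(−‖a−b‖²/2l²). The three
hyperparameters ξ = (σ, l, σ_RBF) are fitted by maximizing the log marginal
likelihood in log-parameter space with analytic gradients and a few seeded
restarts. All output dimensions (genes) share one kernel and one noise
level, so a single Cholesky factor serves every gene.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_solve, cholesky, solve_triangular
from scipy.optimize import minimize
from scipy.spatial.distance import cdist

from .cellpop import CellPopulation
from .dataset import ExpressionDataset
from .errors import DataError, FitError

log = logging.getLogger(__name__)


def rbf_kernel(a: np.ndarray, b: np.ndarray, length_scale: float, sigma_rbf: float) -> np.ndarray:
    """RBF kernel matrix: entry (i,j) = σ_RBF² exp(−‖a_i − b_j‖² / 2l²)."""
    if length_scale <= 0 or sigma_rbf <= 0:
        raise FitError("kernel hyperparameters must be strictly positive")
    a = np.atleast_2d(np.asarray(a, float))
    b = np.atleast_2d(np.asarray(b, float))
    sq = cdist(a, b, "sqeuclidean")
    return sigma_rbf**2 * np.exp(-sq / (2.0 * length_scale**2))


@dataclass
class GPRModel:
    """Fitted GP: training data, hyperparameters and cached Cholesky solve."""

    X_train: np.ndarray        # (m_k, d)
    y_mean: np.ndarray         # (n_out,) per-output training-target mean
    sigma_noise: float
    length_scale: float
    sigma_rbf: float
    L: np.ndarray              # lower Cholesky factor of K + σ²I (+ jitter)
    alpha: np.ndarray          # (m_k, n_out) = (K + σ²I)⁻¹ (Y − μ_V)
    jitter: float


def _chol_with_jitter(K: np.ndarray, jitter: float) -> tuple[np.ndarray, float]:
    j = jitter
    while j <= 1e-4:
        try:
            return cholesky(K + j * np.eye(K.shape[0]), lower=True), j
        except np.linalg.LinAlgError:
            j *= 10.0
    raise FitError("Cholesky factorization failed even with jitter 1e-4")


def _nlml_and_grad(log_params, sq_dists, Yc):
    """Negative log marginal likelihood (summed over outputs) and gradient.

    Parameters are (log σ, log l, log σ_RBF); Yc is centered targets (m, n_out).
    """
    s, l, srbf = np.exp(log_params)
    m, n_out = Yc.shape
    Krbf = srbf**2 * np.exp(-sq_dists / (2.0 * l**2))
    K = Krbf + (s**2 + 1e-12) * np.eye(m)
    try:
        L = cholesky(K, lower=True)
    except np.linalg.LinAlgError:
        return 1e25, np.zeros(3)
    A = cho_solve((L, True), Yc)                     # (m, n_out)
    logdet = 2.0 * np.sum(np.log(np.diag(L)))
    nlml = 0.5 * np.sum(Yc * A) + 0.5 * n_out * (logdet + m * np.log(2 * np.pi))
    Kinv = cho_solve((L, True), np.eye(m))
    # d(NLML)/dθ = ½ tr[(n_out·K⁻¹ − A Aᵀ) dK/dθ]
    W = n_out * Kinv - A @ A.T
    dK_dlog_s = 2.0 * s**2 * np.eye(m)
    dK_dlog_l = Krbf * (sq_dists / l**2)
    dK_dlog_srbf = 2.0 * Krbf
    grad = 0.5 * np.array(
        [np.sum(W * dK_dlog_s), np.sum(W * dK_dlog_l), np.sum(W * dK_dlog_srbf)]
    )
    return nlml, grad


def fit_gpr(
    inputs: np.ndarray,
    targets: np.ndarray,
    init: tuple[float, float, float] | None = None,
    bounds: dict | None = None,
    restarts: int = 3,
    seed: int = 0,
    jitter: float = 1e-8,
) -> GPRModel:
    """Fit GP hyperparameters ξ = (σ, l, σ_RBF) by maximum marginal likelihood.

    Targets are centered per output dimension; one (σ, l, σ_RBF) triple is
    shared across outputs with the likelihood summed over them. Bounds are
    data-driven by default: l within [1e-2, 1e3]× the median pairwise training
    distance, σ and σ_RBF within [1e-4, 1e3]× the pooled target std.
    """
    X = np.atleast_2d(np.asarray(inputs, float))
    Y = np.asarray(targets, float)
    if Y.ndim == 1:
        Y = Y[:, None]
    if X.shape[0] != Y.shape[0]:
        raise DataError("inputs and targets disagree on the number of points")
    if X.shape[0] < 2:
        raise DataError("GPR needs at least 2 training points")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(Y))):
        raise DataError("non-finite values in GPR training data")

    y_mean = Y.mean(axis=0)
    Yc = Y - y_mean
    rng = np.random.default_rng(seed)
    sub = X if X.shape[0] <= 500 else X[rng.choice(X.shape[0], 500, replace=False)]
    pd = cdist(sub, sub)
    med_dist = float(np.median(pd[np.triu_indices_from(pd, k=1)])) or 1.0
    y_scale = float(Yc.std()) or 1e-8

    if bounds is None:
        bounds = {
            "sigma": (1e-4 * y_scale, 1e3 * y_scale),
            "length_scale": (1e-2 * med_dist, 1e3 * med_dist),
            "sigma_rbf": (1e-4 * y_scale, 1e3 * y_scale),
        }
    log_bounds = [
        np.log(bounds["sigma"]),
        np.log(bounds["length_scale"]),
        np.log(bounds["sigma_rbf"]),
    ]
    if init is None:
        init = (0.1 * y_scale, med_dist, y_scale)
    starts = [np.log(np.asarray(init, float))]
    for _ in range(max(0, restarts - 1)):
        starts.append(np.array([rng.uniform(lo, hi) for lo, hi in log_bounds]))

    sq_dists = cdist(X, X, "sqeuclidean")
    best = None
    for x0 in starts:
        x0 = np.clip(x0, [lo for lo, _ in log_bounds], [hi for _, hi in log_bounds])
        res = minimize(
            _nlml_and_grad, x0, args=(sq_dists, Yc), jac=True,
            method="L-BFGS-B", bounds=log_bounds,
        )
        if best is None or res.fun < best.fun:
            best = res
    s, l, srbf = np.exp(best.x)

    K = rbf_kernel(X, X, l, srbf) + s**2 * np.eye(X.shape[0])
    L, used_jitter = _chol_with_jitter(K, jitter)
    alpha = cho_solve((L, True), Yc)
    return GPRModel(
        X_train=X, y_mean=y_mean, sigma_noise=float(s), length_scale=float(l),
        sigma_rbf=float(srbf), L=L, alpha=alpha, jitter=used_jitter,
    )


def predict(model: GPRModel, query: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Posterior mean (q, n_out) and predictive variance diagonal (q,).

    The variance (shared by all outputs, which use one kernel) includes the
    noise term: diag[K** + σ²I − K*(K+σ²I)⁻¹K*ᵀ].
    """
    Xq = np.atleast_2d(np.asarray(query, float))
    if Xq.shape[1] != model.X_train.shape[1]:
        raise DataError(
            f"query dimension {Xq.shape[1]} != training dimension {model.X_train.shape[1]}"
        )
    Ks = rbf_kernel(Xq, model.X_train, model.length_scale, model.sigma_rbf)
    mu = model.y_mean[None, :] + Ks @ model.alpha
    v = solve_triangular(model.L, Ks.T, lower=True)
    var = (
        model.sigma_rbf**2 + model.sigma_noise**2 - np.sum(v**2, axis=0)
    )
    return mu, np.maximum(var, 0.0)


def smooth_population_velocities(
    ds: ExpressionDataset,
    pops: list[CellPopulation],
    mode: str = "per-cluster",
    max_train: int = 1000,
    restarts: int = 3,
    seed: int = 0,
    jitter: float = 1e-8,
    pca_dim: int | None = None,
) -> list[CellPopulation]:
    """Fill each CP's velocity with the GP posterior mean at its centroid.

    ``per-cluster`` (default) fits one GP per GMM cluster on that cluster's
    cells; ``global`` fits a single GP on all cells (subsampled to
    ``max_train`` points, seeded). ``pca_dim`` optionally reduces the kernel
    input space (targets stay full-dimensional). A cluster with fewer than
    2 cells falls back to the mean member velocity.
    """
    X, V = ds.spliced, ds.velocity
    transform = lambda A: A  # noqa: E731
    if pca_dim is not None and pca_dim < X.shape[1]:
        from sklearn.decomposition import PCA

        pca = PCA(n_components=pca_dim, random_state=seed).fit(X)
        transform = pca.transform

    if mode == "global":
        rng = np.random.default_rng(seed)
        idx = np.arange(X.shape[0])
        if idx.size > max_train:
            idx = np.sort(rng.choice(idx, max_train, replace=False))
        model = fit_gpr(
            transform(X[idx]), V[idx], restarts=restarts, seed=seed, jitter=jitter
        )
        centroids = np.vstack([p.centroid for p in pops])
        mu, _ = predict(model, transform(centroids))
        for p, v in zip(pops, mu):
            p.velocity = v
        return pops
    if mode != "per-cluster":
        raise DataError(f"unknown GPR mode '{mode}'")

    by_cluster: dict[int, list[CellPopulation]] = {}
    for p in pops:
        by_cluster.setdefault(p.parent_cluster, []).append(p)
    for k, cluster_pops in sorted(by_cluster.items()):
        cells = np.concatenate([p.members for p in cluster_pops])
        if cells.size < 2:
            log.warning(
                "cluster %d has %d cell(s); using mean member velocity", k, cells.size
            )
            for p in cluster_pops:
                p.velocity = V[p.members].mean(axis=0)
            continue
        rng = np.random.default_rng(seed + k)
        if cells.size > max_train:
            cells = np.sort(rng.choice(cells, max_train, replace=False))
        model = fit_gpr(
            transform(X[cells]), V[cells], restarts=restarts, seed=seed + k,
            jitter=jitter,
        )
        centroids = np.vstack([p.centroid for p in cluster_pops])
        mu, _ = predict(model, transform(centroids))
        for p, v in zip(cluster_pops, mu):
            p.velocity = v
    return pops
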