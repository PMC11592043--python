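"""Gaussian mixture clustering of cells by Expectation–Maximization.

Cells are modelled in the original (normalized) expression space as a
mixture of K Gaussians with diagonal (or spherical) covariance,

    p(x) = Σ_k ω_k N(x | μ_k, diag(σ²_k)),   Σ_k ω_k = 1.

The E step computes posterior responsibilities γ_ir ∝ ω_r N(x_i|μ_r, σ²_r)
(in log space via log-sum-exp); the M step re-estimates weights, means and
per-gene variances from the γ-weighted data. Diagonal covariance is the
default because full covariance is singular whenever genes outnumber cells.
A small variance floor keeps duplicated cells from collapsing a component.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp
from sklearn.cluster import kmeans_plusplus

from .dataset import ExpressionDataset
from .errors import DataError, FitError

log = logging.getLogger(__name__)

VAR_FLOOR = 1e-6


@dataclass
class MixtureModel:
    """Fitted GMM: parameters, responsibilities and hard assignments.

    ``assignments`` are 0-based component indices (argmax responsibility);
    ``log_likelihood_trace`` holds the total data log-likelihood after each
    EM iteration and is non-decreasing up to numerical slack.
    """

    K: int
    weights: np.ndarray          # (K,)
    means: np.ndarray            # (K, n)
    variances: np.ndarray        # (K, n)
    responsibilities: np.ndarray  # (m, K)
    assignments: np.ndarray      # (m,)
    log_likelihood_trace: list[float] = field(default_factory=list)
    covariance: str = "diagonal"

    @property
    def log_likelihood(self) -> float:
        return self.log_likelihood_trace[-1]

    def n_parameters(self) -> int:
        n = self.means.shape[1]
        if self.covariance == "spherical":
            return self.K - 1 + self.K * (n + 1)
        return self.K - 1 + 2 * self.K * n

    def bic(self, m: int) -> float:
        """Bayesian information criterion: −2·loglik + p·log(m)."""
        return -2.0 * self.log_likelihood + self.n_parameters() * np.log(m)


def log_density(x: np.ndarray, mu: np.ndarray, var: np.ndarray) -> float:
    """Log multivariate normal density with diagonal covariance.

    log N(x|μ, diag(σ²)) = −½ Σ_j [ log(2π σ²_j) + (x_j−μ_j)²/σ²_j ].
    """
    x = np.asarray(x, dtype=float)
    mu = np.asarray(mu, dtype=float)
    var = np.asarray(var, dtype=float)
    if np.any(var <= 0):
        raise FitError("non-positive variance in log_density")
    return float(
        -0.5 * np.sum(np.log(2.0 * np.pi * var) + (x - mu) ** 2 / var)
    )


def _log_prob_matrix(X: np.ndarray, means: np.ndarray, variances: np.ndarray) -> np.ndarray:
    """(m, K) matrix of log N(x_i | μ_k, diag(σ²_k)), fully vectorized."""
    const = -0.5 * np.sum(np.log(2.0 * np.pi * variances), axis=1)  # (K,)
    # quadratic term expanded: Σ_j (x_j - μ_j)^2 / v_j
    inv = 1.0 / variances                                            # (K, n)
    quad = (
        (X**2) @ inv.T
        - 2.0 * X @ (means * inv).T
        + np.sum(means**2 * inv, axis=1)[None, :]
    )
    return const[None, :] - 0.5 * quad


def e_step(
    ds_or_X, model: MixtureModel | None = None, *,
    weights=None, means=None, variances=None,
) -> np.ndarray:
    """Posterior responsibilities γ_ir via Bayes' rule, rows summing to 1."""
    X = ds_or_X.spliced if isinstance(ds_or_X, ExpressionDataset) else np.asarray(ds_or_X, float)
    if model is not None:
        weights, means, variances = model.weights, model.means, model.variances
    gamma, _ = _e_step(X, weights, means, variances)
    return gamma


def _e_step(X, weights, means, variances):
    logp = _log_prob_matrix(X, means, variances) + np.log(weights)[None, :]
    norm = logsumexp(logp, axis=1)
    if not np.all(np.isfinite(norm)):
        bad = int(np.flatnonzero(~np.isfinite(norm))[0])
        raise FitError(f"all components underflow for cell index {bad}")
    gamma = np.exp(logp - norm[:, None])
    return gamma, float(norm.sum())


def m_step(
    ds_or_X, gamma: np.ndarray, covariance: str = "diagonal",
    var_floor: float = VAR_FLOOR,
):
    """Weighted parameter updates ω_r, μ_r, σ²_r from responsibilities."""
    X = ds_or_X.spliced if isinstance(ds_or_X, ExpressionDataset) else np.asarray(ds_or_X, float)
    gamma = np.asarray(gamma, dtype=float)
    m = X.shape[0]
    Nk = gamma.sum(axis=0)  # (K,)
    if np.any(Nk < 1e-12):
        raise FitError(
            f"component(s) {np.flatnonzero(Nk < 1e-12).tolist()} collapsed "
            "(total responsibility ~ 0)"
        )
    weights = Nk / m
    means = (gamma.T @ X) / Nk[:, None]
    # E[x^2] - mean^2, numerically guarded then floored
    ex2 = (gamma.T @ (X**2)) / Nk[:, None]
    variances = np.maximum(ex2 - means**2, 0.0) + var_floor
    if covariance == "spherical":
        variances = variances.mean(axis=1, keepdims=True) * np.ones_like(variances)
    return weights, means, variances


def fit_gmm(
    ds_or_X,
    K: int,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 300,
    covariance: str = "diagonal",
    var_floor: float = VAR_FLOOR,
) -> MixtureModel:
    """Fit a K-component GMM by EM from a seeded k-means++ initialization.

    Convergence: relative change of the total log-likelihood below ``tol``.
    A collapsed component (vanishing total responsibility) is re-seeded at
    the cell currently worst explained by the model, keeping K fixed.
    """
    X = ds_or_X.spliced if isinstance(ds_or_X, ExpressionDataset) else np.asarray(ds_or_X, float)
    m, n = X.shape
    if not np.all(np.isfinite(X)):
        raise DataError("non-finite values in expression matrix")
    if K < 1 or K > m:
        raise DataError(f"K={K} must lie in [1, {m}]")
    rng = np.random.default_rng(seed)
    if K == 1:
        centers = X.mean(axis=0, keepdims=True)
    else:
        centers, _ = kmeans_plusplus(X, K, random_state=int(rng.integers(2**31)))
    means = centers.astype(float)
    variances = np.tile(X.var(axis=0) + var_floor, (K, 1))
    weights = np.full(K, 1.0 / K)
    if covariance == "spherical":
        variances = variances.mean(axis=1, keepdims=True) * np.ones_like(variances)
    elif covariance != "diagonal":
        raise DataError(f"unknown covariance structure '{covariance}'")

    trace: list[float] = []
    gamma = None
    for _ in range(max_iter):
        gamma, ll = _e_step(X, weights, means, variances)
        trace.append(ll)
        if len(trace) > 1 and abs(trace[-1] - trace[-2]) < tol * abs(trace[-1]):
            break
        Nk = gamma.sum(axis=0)
        dead = np.flatnonzero(Nk < 1e-12)
        if dead.size:
            worst = int(np.argmin(gamma.max(axis=1)))
            for r in dead:
                log.warning("re-seeding collapsed component %d at cell %d", r, worst)
                means[r] = X[worst]
                variances[r] = X.var(axis=0) + var_floor
                gamma[:, r] = 1e-10
            gamma /= gamma.sum(axis=1, keepdims=True)
        weights, means, variances = m_step(X, gamma, covariance, var_floor)
    gamma, ll = _e_step(X, weights, means, variances)
    if not trace or ll > trace[-1]:
        trace.append(ll)
    return MixtureModel(
        K=K,
        weights=weights,
        means=means,
        variances=variances,
        responsibilities=gamma,
        assignments=np.argmax(gamma, axis=1),
        log_likelihood_trace=trace,
        covariance=covariance,
    )


def select_K(
    ds_or_X,
    K_range,
    seed: int = 0,
    return_scores: bool = False,
    **fit_kwargs,
):
    """Pick K by minimum BIC over ``K_range`` (an iterable of candidate K).

    With ``return_scores=True`` also returns {K: BIC} for inspection.
    """
    X = ds_or_X.spliced if isinstance(ds_or_X, ExpressionDataset) else np.asarray(ds_or_X, float)
    Ks = sorted(set(int(k) for k in K_range))
    if not Ks:
        raise DataError("empty K range")
    m = X.shape[0]
    if Ks[0] < 1 or Ks[-1] > m:
        raise DataError(f"K range {Ks[0]}..{Ks[-1]} outside [1, {m}]")
    scores: dict[int, float] = {}
    for K in Ks:
        model = fit_gmm(X, K, seed=seed, **fit_kwargs)
        scores[K] = model.bic(m)
    best = min(scores, key=scores.get)
    log.info("select_K BIC scores: %s -> K=%d", scores, best)
    if return_scores:
        return best, scores
    return best
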