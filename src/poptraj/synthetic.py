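"""Seeded generator of dyngen-style branching single-cell datasets.

Instead of simulating a gene-regulatory network, each gene follows a smooth
expression program over a latent developmental time t ∈ [0, 1]:

* trunk/linear programs are sums of 2–4 logistic bumps
  μ_g(t) = b_g + Σ_j a_j σ((t − c_j)/w_j);
* after a branch point t_b each terminal branch adds branch-specific bumps
  shifted to vanish at t_b, so expression is continuous at the split;
* the cycle of the cycle-tree topology uses two sinusoidal harmonics of the
  cycle phase φ = t/t_b, exactly periodic, with the four tree branches
  rooted at the cycle's start/end point.

Velocity is the analytic time derivative ∂μ/∂t; spliced counts are
μ + Gaussian noise (``noise_sd`` × per-gene signal sd); unspliced counts
invert the steady-state kinetic relation v = β u − γ s, i.e.
u = (v + γ s)/β clipped at zero. Everything is reproducible from the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .dataset import ExpressionDataset
from .errors import DataError

TOPOLOGIES = ("linear", "bifurcating", "trifurcating", "cycletree")

_N_TERMINAL = {"linear": 1, "bifurcating": 2, "trifurcating": 3, "cycletree": 4}
_T_BRANCH = {"linear": None, "bifurcating": 0.4, "trifurcating": 0.4, "cycletree": 0.25}


@dataclass
class TopologySpec:
    """Conditions for one synthetic dataset (sizes, noise, kinetics, seed)."""

    kind: str
    n_cells: int = 500
    n_genes: int = 50
    noise_sd: float = 0.05
    seed: int = 0
    beta_range: tuple[float, float] = (0.8, 1.2)   # splicing rates β_g
    gamma_range: tuple[float, float] = (0.2, 0.6)  # degradation rates γ_g

    def __post_init__(self) -> None:
        if self.kind not in TOPOLOGIES:
            raise DataError(f"unknown topology '{self.kind}'; pick one of {TOPOLOGIES}")
        if self.n_cells < 50:
            raise DataError("n_cells must be >= 50")
        if self.n_genes < 10:
            raise DataError("n_genes must be >= 10")
        if self.noise_sd < 0:
            raise DataError("noise_sd must be >= 0")


@dataclass
class GenePrograms:
    """Analytic per-gene expression programs μ_g(t, branch) and ∂μ/∂t."""

    kind: str
    t_branch: float | None
    baselines: np.ndarray                     # (n_genes,)
    base_bumps: list[np.ndarray]              # per gene: (J, 3) rows (a, c, w)
    branch_bumps: dict[str, list[np.ndarray]] # terminal branch -> per-gene (J, 3)
    harmonics: np.ndarray | None = None       # cycletree: (n_genes, 2, 2) (amp, phase)

    @property
    def n_genes(self) -> int:
        return len(self.baselines)

    def _bump_sum(self, t: np.ndarray, bumps: np.ndarray, offset_at: float | None):
        a, c, w = bumps[:, 0], bumps[:, 1], bumps[:, 2]
        val = expit((t[:, None] - c) / w) @ a
        if offset_at is not None:
            val = val - float(expit((offset_at - c) / w) @ a)
        return val

    def _bump_deriv(self, t: np.ndarray, bumps: np.ndarray):
        a, c, w = bumps[:, 0], bumps[:, 1], bumps[:, 2]
        s = expit((t[:, None] - c) / w)
        return (s * (1.0 - s)) @ (a / w)

    def _cycle_expr(self, phi: np.ndarray) -> np.ndarray:
        out = np.empty((len(phi), self.n_genes))
        for g in range(self.n_genes):
            (a1, p1), (a2, p2) = self.harmonics[g]
            out[:, g] = (
                self.baselines[g]
                + a1 * np.sin(2 * np.pi * phi + p1)
                + a2 * np.sin(4 * np.pi * phi + p2)
            )
        return out

    def _cycle_deriv_t(self, phi: np.ndarray) -> np.ndarray:
        out = np.empty((len(phi), self.n_genes))
        for g in range(self.n_genes):
            (a1, p1), (a2, p2) = self.harmonics[g]
            out[:, g] = (
                a1 * 2 * np.pi * np.cos(2 * np.pi * phi + p1)
                + a2 * 4 * np.pi * np.cos(4 * np.pi * phi + p2)
            ) / self.t_branch
        return out

    def expression(self, t: np.ndarray, branch: str) -> np.ndarray:
        """Noise-free expression (len(t), n_genes) for cells on one branch."""
        t = np.asarray(t, float)
        if self.kind == "cycletree":
            if branch == "cycle":
                return self._cycle_expr(t / self.t_branch)
            root = self._cycle_expr(np.zeros(1))  # (1, n_genes)
            out = np.tile(root, (len(t), 1))
            for g in range(self.n_genes):
                out[:, g] += self._bump_sum(t, self.branch_bumps[branch][g], self.t_branch)
            return out
        out = np.empty((len(t), self.n_genes))
        for g in range(self.n_genes):
            out[:, g] = self.baselines[g] + self._bump_sum(t, self.base_bumps[g], None)
            if branch in self.branch_bumps:
                out[:, g] += self._bump_sum(t, self.branch_bumps[branch][g], self.t_branch)
        return out

    def velocity(self, t: np.ndarray, branch: str) -> np.ndarray:
        """Analytic ∂μ/∂t, same shape as :meth:`expression`."""
        t = np.asarray(t, float)
        if self.kind == "cycletree":
            if branch == "cycle":
                return self._cycle_deriv_t(t / self.t_branch)
            out = np.empty((len(t), self.n_genes))
            for g in range(self.n_genes):
                out[:, g] = self._bump_deriv(t, self.branch_bumps[branch][g])
            return out
        out = np.empty((len(t), self.n_genes))
        for g in range(self.n_genes):
            out[:, g] = self._bump_deriv(t, self.base_bumps[g])
            if branch in self.branch_bumps:
                out[:, g] += self._bump_deriv(t, self.branch_bumps[branch][g])
        return out


def make_programs(spec: TopologySpec) -> GenePrograms:
    """Draw the per-gene program parameters for a topology (seeded)."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_genes
    t_b = _T_BRANCH[spec.kind]
    baselines = rng.uniform(0.2, 1.0, size=n)

    def draw_bumps(n_bumps, c_lo, c_hi, signed):
        a = rng.uniform(0.5, 2.0, size=n_bumps)
        if signed:
            a *= rng.choice([-1.0, 1.0], size=n_bumps)
        c = rng.uniform(c_lo, c_hi, size=n_bumps)
        w = rng.uniform(0.08, 0.25, size=n_bumps)
        return np.column_stack([a, c, w])

    base_bumps = [draw_bumps(rng.integers(2, 5), -0.1, 1.1, signed=False) for _ in range(n)]
    harmonics = None
    if spec.kind == "cycletree":
        harmonics = np.stack(
            [
                np.column_stack(
                    [rng.uniform(0.3, 1.0, size=2), rng.uniform(0, 2 * np.pi, size=2)]
                )
                for _ in range(n)
            ]
        )
    branch_bumps: dict[str, list[np.ndarray]] = {}
    n_term = _N_TERMINAL[spec.kind]
    if spec.kind != "linear":
        for b in range(1, n_term + 1):
            branch_bumps[f"branch{b}"] = [
                draw_bumps(2, t_b, 1.1, signed=True) for _ in range(n)
            ]
    return GenePrograms(
        kind=spec.kind, t_branch=t_b, baselines=baselines,
        base_bumps=base_bumps, branch_bumps=branch_bumps, harmonics=harmonics,
    )


def draw_kinetics(spec: TopologySpec) -> tuple[np.ndarray, np.ndarray]:
    """Per-gene splicing (β) and degradation (γ) rates, seeded independently."""
    rng = np.random.default_rng(spec.seed + 2)
    beta = rng.uniform(*spec.beta_range, size=spec.n_genes)
    gamma = rng.uniform(*spec.gamma_range, size=spec.n_genes)
    return beta, gamma


def generate(spec: TopologySpec) -> ExpressionDataset:
    """Generate a seeded synthetic dataset with ground truth.

    Cells get uniform latent times; cells past the branch point are split
    uniformly over the terminal branches. Returns an
    :class:`ExpressionDataset` whose ``truth_time``/``truth_branch`` hold
    the generating time and branch label.
    """
    programs = make_programs(spec)
    rng = np.random.default_rng(spec.seed + 1)
    m, n = spec.n_cells, spec.n_genes
    t = rng.uniform(0.0, 1.0, size=m)
    t_b = _T_BRANCH[spec.kind]
    branches = np.empty(m, dtype=object)
    if spec.kind == "linear":
        branches[:] = "branch1"
    else:
        trunk_name = "cycle" if spec.kind == "cycletree" else "trunk"
        pre = t < t_b
        branches[pre] = trunk_name
        n_term = _N_TERMINAL[spec.kind]
        choices = rng.integers(1, n_term + 1, size=m)
        branches[~pre] = [f"branch{c}" for c in choices[~pre]]

    spliced = np.empty((m, n))
    velocity = np.empty((m, n))
    for br in np.unique(branches):
        mask = branches == br
        name = "branch1" if spec.kind == "linear" else str(br)
        if spec.kind == "linear":
            spliced[mask] = programs.expression(t[mask], name)
            velocity[mask] = programs.velocity(t[mask], name)
        else:
            spliced[mask] = programs.expression(t[mask], str(br))
            velocity[mask] = programs.velocity(t[mask], str(br))

    if spec.noise_sd > 0:
        s_sd = spliced.std(axis=0)
        v_sd = velocity.std(axis=0)
        spliced = spliced + rng.standard_normal((m, n)) * (spec.noise_sd * s_sd)
        velocity = velocity + rng.standard_normal((m, n)) * (spec.noise_sd * v_sd)

    beta, gamma = draw_kinetics(spec)
    unspliced = np.maximum((velocity + gamma * spliced) / beta, 0.0)

    width = len(str(m))
    return ExpressionDataset(
        spliced=spliced,
        unspliced=unspliced,
        velocity=velocity,
        cell_ids=[f"cell_{i:0{width}d}" for i in range(m)],
        gene_ids=[f"gene_{j:03d}" for j in range(n)],
        truth_time=t,
        truth_branch=branches,
    )
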