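# poptraj

Population-level trajectory inference for single-cell transcriptomics,
driven by RNA velocity.

## The problem

Single-cell RNA-seq captures a static snapshot of a developing tissue.
Trajectory inference (TI) reconstructs the underlying dynamics: an ordering
of cells along developmental paths (pseudo-time) and the branching
structure connecting them. RNA velocity — the time derivative of spliced
mRNA abundance estimated from the spliced/unspliced read balance — gives
each cell a *direction* in expression space, which resolves the ambiguity
of similarity-only TI. But per-cell velocities are noisy, and methods that
work cell-by-cell inherit that noise.

`poptraj` works at the level of *cell populations*: small, metacell-like
sub-clusters that preserve local structure while averaging out single-cell
noise. Given three aligned cells×genes matrices — spliced counts **S**,
unspliced counts **U** and velocity **V** (computed upstream, e.g. with
scVelo or velocyto) — it:

1. clusters cells with a Gaussian mixture model
   p(x) = Σₖ ωₖ N(x | μₖ, diag(σₖ²)) fitted by EM in the original
   expression space;
2. refines each cluster into cell populations (CPs) of ≈20 cells by
   seeded k-means, with centroids X*;
3. smooths velocity onto the CPs with Gaussian-process regression:
   μ* = μ_V + Σ\*(Σ + σ²I)⁻¹(V − μ_V) under an RBF kernel
   k(a,b) = σ²_RBF exp(−‖a−b‖²/2l²), hyperparameters (σ, l, σ_RBF) by
   maximum marginal likelihood;
4. links CPs in a directed weighted kNN graph with edge weight
   e_{s,q} = λ^{l_α + β·l_d} / λ, where l_α = 1 − cos∠(X*_q − X*_s, v_s)
   penalizes edges that defy the local velocity and l_d = d_{s,q}/d_max
   penalizes long jumps;
5. finds trajectories as source→sink Floyd–Warshall shortest paths chosen
   greedily for coverage; and
6. assigns each cell a pseudo-time in [0, 1]: its population's path
   position, refined within the population by projecting the cell onto the
   velocity line W(t) = X*_s + v_s(t − t_s).

A seeded synthetic-data module generates dyngen-style benchmark topologies
(linear, bifurcating, trifurcating, cycle-tree) with ground-truth time and
branch labels, analytic velocities, and spliced/unspliced layers obeying
the kinetic relation v = βu − γs, so the whole pipeline is testable
offline. Accuracy is scored with an absolute-numerator, tie-corrected
Kendall τ_b ∈ [0, 1] and Spearman's ρ, per path and averaged.

## Worked example

```sh
poptraj --quiet simulate --topology bifurcating --cells 300 --genes 30 \
        --seed 7 --out demo_data
poptraj --quiet run demo_data --seed 7 --out demo_out
```

prints

```
wrote bifurcating dataset (300 cells x 30 genes) to demo_data
2 trajectory(ies); artifacts in demo_out
mean Kendall tau_b = 0.9788, mean Spearman rho = 0.9982 over 2 path(s)
```

Two trajectories were detected — one per branch of the bifurcation — and
the inferred per-cell pseudo-time agrees with the simulation's hidden
developmental clock at τ_b ≈ 0.98 (1 = perfect ordering). `demo_out/`
contains the per-cell table (`cell_id, population_id, path_id,
pseudotime`), the population graph as edge-list CSV and GraphML, a
per-path JSON, the metrics JSON and the resolved config. Cells whose
population lies on no selected path have an empty pseudo-time field.

The same run is available from Python:

```python
from poptraj import TopologySpec, generate, run_pipeline, RunConfig

ds = generate(TopologySpec("bifurcating", n_cells=300, n_genes=30, seed=7))
result = run_pipeline(ds, RunConfig(seed=7))
print(result.evaluation["kendall"], result.evaluation["spearman"])
```

Real datasets are supplied as Matrix-Market/CSV triplets
(`spliced`, `unspliced`, `velocity` + id files) or an `.h5ad` container
with layers of those names; see `poptraj run --help`.

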