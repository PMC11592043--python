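# Methods

This note records the model, the numerical choices, the defaults and their
rationale, and what the synthetic benchmark does and does not establish.

## Model and procedure

**Inputs.** Three aligned cells×genes matrices: spliced expression S,
unspliced counts U and RNA velocity V, plus identifiers. Velocity is
strictly an input; estimating it (velocyto/scVelo steady-state or dynamical
models) is out of scope. The pipeline's default configuration treats S as
already normalized (the usual scVelo-preprocessed output); for raw counts,
`io.preprocess: true` enables gene filtering (total spliced counts ≥
`min_counts`, default 20), per-cell library-size normalization to the
median total, log1p, and restriction to the `n_top_genes` (default 2000)
highest-dispersion genes. The velocity layer is subset together with the
other layers but never rescaled or log-transformed: a monotone transform of
expression would break the linear kinetic interpretation of v.

**GMM clustering.** Cells are modelled as a K-component Gaussian mixture in
the original (optionally HVG-restricted) expression space — deliberately
not a PCA embedding, so population centroids and velocities live in the
same coordinates as the data. Covariance is diagonal by default (full
covariance is singular whenever genes outnumber cells; spherical is
available). EM alternates log-space responsibilities (log-sum-exp) with
weighted updates; initialization is seeded k-means++ centers with global
variances and uniform weights. Convergence: relative log-likelihood change
< 1e-6, at most 300 iterations. A variance floor of 1e-6 on every σ²
entry prevents singularities on duplicated cells. A component whose total
responsibility vanishes is re-seeded at the currently worst-explained cell,
keeping K fixed. K is either user-fixed (e.g. a known cell-type count) or
chosen by minimum BIC = −2·loglik + p·log m with p = K−1+2Kn over a range
(default 2–8). On trajectory-like data there are no discrete clusters and
BIC mainly sets granularity; the downstream population refinement makes the
result insensitive to the exact K.

**Cell populations.** Each cluster k is split into
s_k = max(1, round(|C_k| / target_pop_size)) populations by seeded k-means
(target_pop_size default 20 — small enough to retain cell-specific
structure, large enough to average noise; the refinement rule itself is a
design choice, as only the existence of a cluster→populations mapping is
prescribed by the method). When a cluster has fewer distinct points than
s_k (duplicated cells), members are split evenly instead. Population ids
are deterministic: sorted by parent cluster, then smallest member index.

**GP velocity smoothing.** Velocities at population centroids are the
posterior mean of a GP regression of V on S over the cluster's cells, with
an RBF kernel and Gaussian noise. All genes share one kernel and one noise
level, so a single Cholesky factorization of (K + σ²I) serves every output
column; the marginal likelihood is summed over outputs and maximized over
(log σ, log l, log σ_RBF) by L-BFGS-B with analytic gradients and 3 seeded
restarts. Bounds are data-driven: l within [1e-2, 1e3]× the median pairwise
training distance, σ and σ_RBF within [1e-4, 1e3]× the pooled target sd.
One GP per GMM cluster is the default (locality plus O(m_k³) instead of
O(m³) cost); a `global` mode fits one GP on all cells, subsampled to
`max_train` (default 1000). Cholesky failures escalate jitter from 1e-8 to
1e-4 before erroring. Clusters with < 2 cells fall back to the mean member
velocity. An optional `pca_dim` reduces the kernel *input* space only, for
very wide matrices.

**Population graph.** Each population gets directed edges to its k (default
10) nearest populations by centroid distance. The edge s→q costs
e = λ^{l_α + β·l_d}/λ with λ = 3, β = 1:

* l_α = 1 − cos α, cos α = (X*_q − X*_s)ᵀ v_s / (‖X*_q − X*_s‖ ‖v_s‖).
  The displacement is taken *toward the target* so that an edge pointing
  where the source's velocity points scores l_α = 0 (best) and one pointing
  against it scores 2 (worst).
* l_d = d_{s,q}/d_max, with d_max the maximum over all retained candidate
  edges globally, keeping l_d comparable across the graph.

The exponential form makes the weight strictly increasing in both
dissimilarities for λ > 1 and spreads the dynamic range nonlinearly;
λ^0/λ = 1/λ is the floor cost of a perfect edge. With `prune_backward`
(default on), edges at more than 90° to the source velocity (l_α > 1) are
removed, so paths cannot run against the flow. A zero-velocity population
gets neutral l_α = 1 with a warning rather than aborting the run;
coincident-centroid candidate edges are skipped.

**Trajectories.** All-pairs shortest paths by Floyd–Warshall (vectorized
over the intermediate-node loop; handles negative edge weights; a negative
cycle raises). Ties resolve deterministically: intermediates are scanned in
ascending population id with strict improvement only. Path selection among
the all-pairs results is a genuinely open design point; the rule used:
candidate sources are in-degree-0 nodes (else minimal in-degree), candidate
sinks out-degree-0 nodes (else maximal-distance targets), and source→sink
shortest paths are selected greedily by most newly covered populations
(ties: lower mean edge weight, then smaller endpoints) until 95% of the
coverable populations are covered or `max_paths` (default 20) is reached.
Because the edge cost has a positive floor, shortest paths take moderately
long hops and may skip intermediate populations; skipped ones are picked up
by later paths, and each path remains internally ordered. Populations are
assigned to the first path covering them; cells of unassigned populations
get an empty pseudo-time field (logged).

**Pseudo-time.** Within a path, population s at position j gets t_s = j —
integer positions rather than arc length, because the projection offset δ
has expression/velocity units that are incomparable to arc length and is
used only ordinally. Each member cell is projected onto the population's
velocity line, δ = (x − X*_s)·v_s/‖v_s‖², and δ is rescaled within the
population to (−0.45, +0.45) by dividing by max|δ| (0 if all δ = 0). The
0.45 bound keeps adjacent populations' cells from interleaving, so the
population-level ordering stays authoritative. Raw times t_s + δ̃ are then
min–max normalized to [0, 1] per path.

**Evaluation.** Kendall τ_b with the absolute-value numerator
|C−D| / √((C+D+T_pred)(C+D+T_true)) ∈ [0, 1] (direction-blind: a path
traversed backwards is still a correct ordering), and Spearman ρ as the
Pearson correlation of average ranks. Both are undefined (error) for
all-tied vectors. With multiple paths, each path is scored on its own
cells and the unweighted mean across paths is reported; the aggregation
rule (mean, not weighted or best-path) is this package's choice.

## Synthetic data

The generator emulates the *outputs* of a branching-dynamics simulator
rather than simulating a gene-regulatory network: each gene follows a
smooth program over latent time t ∈ [0, 1] (2–4 logistic bumps; amplitudes
0.5–2 over baselines 0.2–1; widths 0.08–0.25), branch-specific bumps are
offset to vanish at the branch point (t_b = 0.4 for bi-/trifurcating
topologies) so expression is continuous at splits, and the cycle-tree's
cycle (t_b = 0.25, four branches rooted at the cycle's start) uses two
sinusoidal harmonics of the cycle phase, exactly periodic. Velocity is the
analytic ∂μ/∂t; spliced = μ + Gaussian noise at `noise_sd` (default 0.05)
× the per-gene signal sd; unspliced inverts the steady-state relation
u = (v + γs)/β (β ∈ [0.8, 1.2], γ ∈ [0.2, 0.6] per gene), clipped at 0.
Defaults: 500 cells, 50 genes.

What this emulates: smooth branch-specific expression with a consistent
velocity field, known topology and a hidden clock — exactly the structure
the method consumes. What it does not: count noise (no negative binomial or
dropout), batch effects, doublets, or velocity-estimation artifacts
(systematic sign errors, boundary effects). Passing benchmarks here shows
the inference machinery recovers orderings from clean-to-moderately-noisy
velocity fields; it does not certify robustness to misestimated velocities
on real data.

## Problem sizes and determinism

Benchmark runs use 500–600 cells × 50 genes, sizes at which every stage is
exact (no subsampling triggers) and a full run takes a few seconds on one
CPU. One global seed derives fixed per-stage offsets (GMM +11, populations
+23, GPR +37); identical (data, config, seed) triples give byte-identical
outputs.

## Known limitations

* The CP-skipping behaviour of shortest paths means coverage per path can
  be sparse; pseudo-time is only assigned to populations on selected paths.
* BIC-based K selection on continuum data is a granularity knob, not a
  model-selection truth; fix K when cell-type counts are known.
* Per-cluster GPs ignore cross-cluster continuity of the velocity field;
  the global mode addresses this at O(m³) cost.
* The cycle of the cycle-tree topology is recovered as overlapping linear
  paths, not as an explicit cyclic object.
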