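# Methods

## The model

`muhmds` embeds a set of n samples, described either by feature vectors, a
precomputed dissimilarity matrix, or a graph, into D-dimensional hyperbolic
space. Hyperbolic space is the natural continuous analogue of a tree: the
volume of a ball grows exponentially with its radius, so nested, branching
structure — developmental lineages in single-cell transcriptomics, lexical
taxonomies, phylogenies — can be represented with far less distortion than
in Euclidean space of the same dimension. In such embeddings hierarchical
depth accumulates along the radial direction, which makes the hyperbolic
radius a useful proxy for developmental progression.

Coordinates live on the unit-curvature hyperboloid (Lorentz model): the
sheet g_ab x^a x^b = 1, g = diag(1, −1, …, −1), in (D+1)-dimensional
Minkowski space, with geodesic distance d(x, y) = arccosh(⟨x, y⟩_L). Only
the D spacelike components are free parameters; x_0 = sqrt(1 + |x⃗|²) is
always derived, so every point satisfies the constraint identically and no
projection step is needed during optimization. The Poincaré ball model is
used for conversions, Möbius addition and the ball form of the log map;
distances agree across models to 1e-8 in the test suite.

### Bayesian hyperbolic MDS

The generative model treats the observed dissimilarities as noisy readouts
of geodesic distances subject to one global scale:

    δ_ij = d_ij / λ + ε_ij,   ε_ij ~ N(0, σ_i² + σ_j²).

Fitting λ in unit-curvature coordinates is equivalent to fitting the
curvature of the space: curvature only matters relative to the scale at
which the data is observed. Input dissimilarities are normalized so
max δ_ij = 2, which makes λ interpretable as the radius of the embedded
cloud. Each point carries one uncertainty σ_i with an inverse-gamma prior
(a = 2, b = 0.5); λ carries a normal prior of scale σ_λ = 10 whose log is
multiplied by the number of pairs so the prior strength survives the
large-n limit. The resulting negative log-posterior

    L = ½ Σ_{i<j} [ (d_ij/λ − δ_ij)²/(σ_i²+σ_j²) + ln(σ_i²+σ_j²) ]
        + n(n−1)/(4σ_λ²) λ² + Σ_i [ (a+1) ln σ_i + b/σ_i ]

is minimized (MAP estimation, no posterior sampling) with L-BFGS using the
exact analytic gradient, which a finite-difference check pins to 1e-5
relative accuracy.

### The multiscale (global-local) algorithm

Evaluating all O(n²) pairwise arccosh distances at every optimizer step is
what makes plain hyperbolic MDS prohibitive. The multiscale algorithm is an
adiabatic approximation: slow global degrees of freedom (cluster centroid
positions) are fitted once and then frozen while fast local degrees of
freedom (each cluster's members) relax around them.

1. **Cluster** the samples (seeded k-means on features; hand-rolled
   Voronoi-iteration k-medoids when only a dissimilarity matrix exists).
2. **Size control**: clusters smaller than `size_min` (default 3) are
   dissolved into an outlier set; clusters larger than `size_max` (default
   ceil(n/5), capped at 2000) are recursively re-clustered with
   k = ceil(size/size_max).
3. **Global stage**: the K×K centroid distance matrix is embedded with the
   full Bayesian model.
4. **Local stage**: each cluster's members are embedded by the "relax"
   optimization — only the new points (and their σ_i) move, against fixed
   anchors consisting of the cluster's own centroid plus its α nearest
   neighboring centroids (α = 20 by default); λ is frozen at the
   global-stage value so every local problem shares one metric scale.
   Clusters are independent, so this stage parallelizes (joblib behind the
   `parallel` flag); per-cluster seeds derive from the master seed via
   `SeedSequence`, so serial and parallel runs agree bitwise.
5. **Integrate** local results in input row order and **remap outliers**:
   each excluded sample is fitted alone against its α nearest embedded
   samples as anchors.

Distances between samples of non-neighboring clusters are never optimized
directly; they are inherited from the frozen centroid geometry. This is
accurate whenever within-cluster displacements are much smaller than
centroid separations, and the package verifies it numerically: on blob data
the maximum relative error of the substituted cross-cluster dissimilarities
falls monotonically with the spread/separation ratio and is below 5% at a
ratio of 0.01.

With k clusters the global stage costs O(k²) per iteration and the serial
local stage O(n²/k); minimizing c₁k² + c₂n²/k gives k* ∝ n^(2/3) and a
total cost ∝ n^(4/3). With perfectly parallel local stages the local term
becomes (n/k)² and k* ∝ n^(1/2). `k="auto"` applies round(n^(2/3))
(serial) or round(n^(1/2)) (parallel), clipped to [2, n/2]. Inputs with
n ≤ 4 (or an effective single cluster) fall back to the plain full fit.

### Anchor choice in the local stage

The neighbor sets ξ_{m,α} exclude the cluster's own centroid, but the local
objective must constrain each member's distance to its own centroid — that
is the quantity the approximation argument needs directly optimized — so
the own centroid is always prepended to the anchor list, giving α+1 anchors
per cluster. Anchors are treated as noiseless (their σ is not re-fitted and
does not enter the residual weight); only the new points' σ_i are free.

## Numerical choices

- **Initialization**: spacelike coordinates i.i.d. normal with std 0.1
  from a seeded generator (local stages initialize near the parent
  centroid's position); λ starts at 1, σ_i at the prior mode b/(a+1).
- **Two-phase schedule**: the full fit first optimizes coordinates and λ
  with σ frozen at the prior mode, then refines everything jointly. With a
  joint fit from the start, early large residuals inflate the σ_i, which
  damps the coordinate gradients by 1/σ² and stalls the expansion of the
  point cloud out of its small initial ball; the warm-up phase removes
  that plateau.
- **Positivity**: λ = exp(z) and σ = 10⁻⁴ + exp(z). The offset keeps
  ln(σ_i² + σ_j²) finite in the exact-fit limit; box constraints are
  deliberately avoided because an active bound degrades L-BFGS's curvature
  estimate.
- **Transcendental guards**: Minkowski inner products are clamped to
  [1, ∞) before arccosh and ball norms strictly inside the unit ball
  before arctanh; the 0/0 limit of the log map at the origin returns the
  zero vector explicitly.
- **Stopping**: gradient tolerance 1e-6, at most 2000 iterations per
  phase; the joint refinement phase uses a relative function tolerance of
  1e-9 (its σ refinement tail moves the loss but not the coordinates),
  the other fits 1e-12.
- **Outlier remap restarts**: a single point fitted against a one-sided
  cone of anchors can have a spurious minimum; each outlier is fitted from
  four deterministic starts (nearest anchor, anchor mean, two seeded
  random anchors) keeping the lowest loss.
- **Gauge fixing**: the loss is invariant under hyperbolic isometries, so
  radius-based analyses would otherwise be ill-defined. By default the
  final configuration is translated by the Lorentz boost that carries the
  normalized ambient mean (a Fréchet-mean proxy) to the origin; all
  pairwise distances are preserved to machine precision (`center=False`
  disables this).
- **Rank ties** in the co-ranking matrix break by stable index order — a
  measure-zero event for continuous data, pinned for reproducibility.
- **Q-curve split**: the local/global split scale K* maximizes the
  chance-corrected curve Q_NX(K) − K/(n−1) (the local continuity
  meta-criterion); Q_local and Q_global are the means of Q_NX below and
  above K*. Other split conventions shift both values by a constant
  offset; comparisons across runs of this package are consistent.
- **Log map forms**: the Lorentz form arccosh(x₀)·x⃗/|x⃗| has norm equal to
  the geodesic distance; the ball form arctanh(|y|)·y/|y| has half that
  norm (conformal factor 2 at the ball origin). The package returns the
  Lorentz normalization and the tests check the two agree after scaling.

## Synthetic data

The generators produce every input class the pipeline accepts, with ground
truth for validation. They define the package's study conditions:

- `sample_hyperbolic_cloud`: points uniform with respect to hyperbolic
  volume (radial density ∝ sinh^(D−1) r, inverse-CDF sampling) inside a
  ball, plus the exact distance matrix — the recovery oracle. Recovery
  experiments use n = 300, radius 3.
- `generate_branching_data`: a prototype tree grown by a Gaussian random
  walk (child = parent + step of scale `step_size`), each node emitting
  samples with isotropic noise; labels carry node, generation depth and a
  ±1 first-branch code. The defaults (depth 4, binary, step/noise = 5)
  emulate the geometry of simulated differentiation hierarchies —
  a common-progenitor state branching into discrete fates. The
  multiscale-versus-full comparison uses 500 such samples in 50 features.
- `generate_blobs`: isotropic Gaussians with controlled spread/separation
  ratio — the small parameter of the approximation theorem, probed at
  s/S ∈ {0.3, 0.1, 0.03, 0.01}.
- `generate_balanced_tree`: edge list of a fully balanced rooted tree;
  depth 5, branching 2 (63 nodes) for the graph-embedding check.

What these generators do *not* emulate: scRNA-seq count noise (dropout,
negative binomial overdispersion), batch effects, doublets, or the
library-size normalization pipeline of real single-cell data. Passing the
recovery and parity tests shows the embedding machinery is correct and the
multiscale approximation is tight under its stated assumption; it does not
certify biological conclusions on any particular real dataset, where the
dissimilarity definition itself (preprocessing, PCA depth, metric choice)
dominates.

## Problem sizes and measured behavior

The test suite and acceptance script run at desk scale, chosen so the full
(quadratic) reference fit is still computable for comparison: recovery at
n = 300, multiscale-versus-full parity at n = 500, the timing trade-off at
n = 2000 over k ∈ {5, 20, 80, 160, 320, 640} (the measured curve is
U-shaped with its minimum near the n^(2/3) rule, which predicts k ≈ 159).
The cost-model exponents are obtained by numeric minimization at
n ∈ {10³, 10⁴, 10⁵} and log-log slope fitting, not from wall-clock
measurements, which are hardware-dependent.

## Known limitations

- MAP only: the σ_i are point estimates, not posterior spreads.
- A single global round: centroid positions are never revisited after the
  local stages. The config exposes `global_rounds` as a hook but the
  implementation treats one round as sufficient, matching its validation.
- The k-medoids used for distance-matrix input is Voronoi iteration with
  farthest-point seeding, not full PAM; for pathological dissimilarities
  its partition can be worse than PAM's.
- Embeddings are identified only up to isometry; the centering gauge makes
  radii comparable across runs but the angular orientation remains
  arbitrary (fit directions with `lineage.fit_projection_axis` rather than
  comparing raw coordinates).
- `fit_relax` inherits λ from the global stage; embedding new data against
  anchors from a *different* fit (transfer) is unsupported.
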