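"""Multiscale global-local hyperbolic embedding (MuH-MDS orchestration).

Evaluating all O(n^2) nonlinear distances at every optimizer step is what
makes plain hyperbolic MDS prohibitive at scale.  The multiscale algorithm
sidesteps this by an adiabatic split:

1. partition the samples into k clusters (with cluster-size control),
2. embed the K cluster centroids globally with the full Bayesian model,
3. embed each cluster's members locally, against their own centroid and
   the alpha nearest neighboring centroids held *fixed* as anchors,
4. integrate all local results and remap excluded outliers last.

Distances between samples of non-neighboring clusters are never optimized
directly; they are inherited from the frozen centroid geometry, which is a
valid approximation whenever within-cluster displacements are much smaller
than centroid separations.  Because each local problem only sees its own
cluster plus a fixed anchor set, the local stage parallelizes trivially,
and the serial cost model c1*k^2 + c2*n^2/k is minimized at k ~ n^(2/3)
(total cost ~ n^(4/3)); with perfect parallelism the local term becomes
(n/k)^2 and the optimum moves to k ~ n^(1/2).
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.spatial.distance import cdist, pdist, squareform
from sklearn.cluster import KMeans

from . import bhmds
from .bhmds import EmbeddingResult, FitConfig, PriorConfig, fit_bhmds, fit_relax
from .data_io import InputBundle, graph_to_distances
from .geometry import HyperbolicPointSet, center_points

__all__ = [
    "MultiscaleConfig",
    "ClusterPartition",
    "auto_cluster_count",
    "serial_cost",
    "parallel_cost",
    "optimal_cluster_count",
    "cost_model_exponents",
    "cluster_samples",
    "kmedoids",
    "enforce_size_bounds",
    "build_centroid_distances",
    "build_local_distances",
    "estimate_distances_from_matrix",
    "approximate_dissimilarities",
    "run_muhmds",
    "map_outliers",
]


# ---------------------------------------------------------------------------
# analytic cost model


def serial_cost(k: float, n: float, c1: float = 1.0, c2: float = 1.0) -> float:
    """Serial cost t(k) = c1 k^2 (global) + c2 n^2 / k (local, sequential)."""
    return c1 * k * k + c2 * n * n / k


def parallel_cost(k: float, n: float, c1: float = 1.0, c2: float = 1.0) -> float:
    """Parallel cost t(k) = c1 k^2 + c2 (n/k)^2 (local stages concurrent)."""
    return c1 * k * k + c2 * (n / k) ** 2


def optimal_cluster_count(n: float, parallel: bool = False, c1: float = 1.0, c2: float = 1.0):
    """Numerically minimize the cost model over k; returns (k_opt, t_opt)."""
    cost = parallel_cost if parallel else serial_cost
    res = minimize_scalar(
        lambda lk: cost(np.exp(lk), n, c1, c2),
        bounds=(0.0, np.log(n)),
        method="bounded",
        options={"xatol": 1e-10},
    )
    k_opt = float(np.exp(res.x))
    return k_opt, float(cost(k_opt, n, c1, c2))


def cost_model_exponents(ns=(1e3, 1e4, 1e5), parallel: bool = False):
    """Log-log slopes of the optimal k and optimal time against n.

    For the serial model the slopes are 2/3 and 4/3; for the parallel
    model the k slope is 1/2.  Returns ``(k_exponent, t_exponent)``.
    """
    ks, ts = zip(*(optimal_cluster_count(n, parallel) for n in ns))
    ln = np.log(np.asarray(ns, dtype=float))
    k_exp = float(np.polyfit(ln, np.log(ks), 1)[0])
    t_exp = float(np.polyfit(ln, np.log(ts), 1)[0])
    return k_exp, t_exp


def auto_cluster_count(n: int, parallel: bool = False) -> int:
    """Cluster count rule: round(n^(2/3)) serial, round(n^(1/2)) parallel,
    clipped to [2, n/2]."""
    if n < 2:
        raise ValueError("need at least 2 samples")
    k = round(n ** (1.0 / 2.0 if parallel else 2.0 / 3.0))
    return int(np.clip(k, 2, max(2, n // 2)))


# ---------------------------------------------------------------------------
# configuration and partition containers


@dataclass(frozen=True)
class MultiscaleConfig:
    """Controls for one multiscale embedding run.

    ``k`` may be an integer or "auto" (the n^(2/3) / n^(1/2) rule).
    ``alpha`` is the number of neighboring centroids anchoring each local
    fit.  Clusters smaller than ``size_min`` are dissolved into the
    outlier set and remapped at the end; clusters larger than ``size_max``
    (default n/5, capped at 2000) are recursively subdivided.
    """

    k: int | str = "auto"
    alpha: int = 20
    size_min: int = 3
    size_max: int | None = None
    dim: int = 3
    seed: int = 0
    parallel: bool = False
    center: bool = True
    global_rounds: int = 1
    max_iters: int = 2000
    gtol: float = 1e-6
    init_scale: float = 0.1

    def __post_init__(self):
        if self.alpha < 1:
            raise ValueError("alpha must be >= 1")
        if self.size_max is not None and self.size_min > self.size_max:
            raise ValueError("size_min must not exceed size_max")
        if isinstance(self.k, str) and self.k != "auto":
            raise ValueError(f"k must be an integer or 'auto', got {self.k!r}")

    def resolve_k(self, n: int) -> int:
        if self.k == "auto":
            return auto_cluster_count(n, self.parallel)
        k = int(self.k)
        if not (1 <= k <= n):
            raise ValueError(f"k={k} outside [1, {n}]")
        return k

    def resolve_size_max(self, n: int) -> int:
        if self.size_max is not None:
            return self.size_max
        return max(self.size_min, min(-(-n // 5), 2000))


@dataclass
class ClusterPartition:
    """Assignment of samples to clusters, with centroids and neighbor sets.

    ``assignments[i]`` is the cluster id of sample i, or -1 for outliers.
    ``centroids`` are feature-space means; when the input is a
    dissimilarity matrix there is no feature space and ``medoid_ids``
    holds, per cluster, the member minimizing total within-cluster
    dissimilarity (a centroid surrogate accurate to the within-cluster
    spread).  ``neighbor_sets[m]`` lists the ids of the min(alpha, K-1)
    nearest other centroids, ascending by centroid distance.
    """

    assignments: np.ndarray
    centroids: np.ndarray | None = None
    medoid_ids: np.ndarray | None = None
    neighbor_sets: list = field(default_factory=list)

    @property
    def n_clusters(self) -> int:
        return int(self.assignments.max()) + 1 if np.any(self.assignments >= 0) else 0

    @property
    def outliers(self) -> np.ndarray:
        return np.flatnonzero(self.assignments < 0)

    def members(self, m: int) -> np.ndarray:
        return np.flatnonzero(self.assignments == m)

    def sizes(self) -> np.ndarray:
        return np.bincount(self.assignments[self.assignments >= 0], minlength=self.n_clusters)


def _relabel(assignments: np.ndarray) -> np.ndarray:
    """Compact cluster ids to 0..K-1 keeping -1 for outliers."""
    out = np.full_like(assignments, -1)
    for new, old in enumerate(np.unique(assignments[assignments >= 0])):
        out[assignments == old] = new
    return out


def _centroid_matrix(features: np.ndarray, assignments: np.ndarray) -> np.ndarray:
    K = int(assignments.max()) + 1
    return np.stack([features[assignments == m].mean(axis=0) for m in range(K)])


def _neighbor_sets(centroid_dist: np.ndarray, alpha: int) -> list:
    K = centroid_dist.shape[0]
    sets = []
    for m in range(K):
        order = np.argsort(centroid_dist[m], kind="stable")
        order = order[order != m][: min(alpha, K - 1)]
        sets.append(order)
    return sets


# ---------------------------------------------------------------------------
# clustering


def cluster_samples(features: np.ndarray, config: MultiscaleConfig) -> ClusterPartition:
    """Partition samples by seeded k-means (k-means++ init, 10 restarts)."""
    features = np.asarray(features, dtype=float)
    n = features.shape[0]
    if n < 2:
        raise ValueError("need at least 2 samples to cluster")
    if not np.all(np.isfinite(features)):
        raise ValueError("features must be finite")
    k = config.resolve_k(n)
    if n < k:
        raise ValueError(f"cannot form {k} clusters from {n} samples")
    if k == 1:
        assignments = np.zeros(n, dtype=int)
    else:
        km = KMeans(n_clusters=k, n_init=10, random_state=config.seed % 2**31)
        assignments = km.fit_predict(features)
        assignments = _relabel(assignments)
    centroids = _centroid_matrix(features, assignments)
    cd = squareform(pdist(centroids)) if centroids.shape[0] > 1 else np.zeros((1, 1))
    return ClusterPartition(
        assignments=assignments,
        centroids=centroids,
        neighbor_sets=_neighbor_sets(cd, config.alpha),
    )


def kmedoids(delta: np.ndarray, k: int, seed: int = 0, max_iter: int = 100) -> np.ndarray:
    """Voronoi-iteration k-medoids on a dissimilarity matrix.

    Greedy farthest-point style seeding from a random start, then
    alternating assignment and medoid update until stable.  Returns the
    assignment vector.
    """
    delta = np.asarray(delta, dtype=float)
    n = delta.shape[0]
    if not np.allclose(delta, delta.T, atol=1e-8):
        raise ValueError("k-medoids requires a symmetric dissimilarity matrix")
    if k >= n:
        return np.arange(n)
    rng = np.random.default_rng(seed)
    medoids = [int(rng.integers(n))]
    for _ in range(k - 1):
        d_to_near = delta[:, medoids].min(axis=1)
        d_to_near[medoids] = -1.0
        medoids.append(int(np.argmax(d_to_near)))
    medoids = np.asarray(medoids)

    assignments = np.argmin(delta[:, medoids], axis=1)
    for _ in range(max_iter):
        new_medoids = medoids.copy()
        for m in range(k):
            members = np.flatnonzero(assignments == m)
            if len(members) == 0:
                continue
            sub = delta[np.ix_(members, members)]
            new_medoids[m] = members[int(np.argmin(sub.sum(axis=1)))]
        new_assignments = np.argmin(delta[:, new_medoids], axis=1)
        if np.array_equal(new_medoids, medoids) and np.array_equal(
            new_assignments, assignments
        ):
            break
        medoids, assignments = new_medoids, new_assignments
    return _relabel(assignments)


def _cluster_distance_matrix(delta, k, seed, alpha):
    assignments = kmedoids(delta, k, seed)
    part = ClusterPartition(assignments=assignments)
    _update_medoids(delta, part, alpha)
    return part


def _update_medoids(delta, part, alpha):
    K = part.n_clusters
    medoids = np.empty(K, dtype=int)
    for m in range(K):
        members = part.members(m)
        sub = delta[np.ix_(members, members)]
        medoids[m] = members[int(np.argmin(sub.sum(axis=1)))]
    part.medoid_ids = medoids
    cd = delta[np.ix_(medoids, medoids)]
    part.neighbor_sets = _neighbor_sets(cd, alpha)


def enforce_size_bounds(
    partition: ClusterPartition,
    config: MultiscaleConfig,
    features: np.ndarray | None = None,
    delta: np.ndarray | None = None,
) -> ClusterPartition:
    """Dissolve undersized clusters into outliers; subdivide oversized ones.

    Clusters below ``size_min`` are excluded from the global-local stages
    entirely (their members become outliers, remapped at the end).
    Clusters above ``size_max`` are re-clustered with k = ceil(size /
    size_max), recursively, until every size fits.  Centroids/medoids and
    neighbor sets are recomputed afterwards.
    """
    if features is None and delta is None:
        raise ValueError("need features or a dissimilarity matrix")
    n = len(partition.assignments)
    size_min = config.size_min
    size_max = config.resolve_size_max(n)
    if size_min > size_max:
        raise ValueError("size_min must not exceed size_max")

    assignments = partition.assignments.copy()
    next_id = int(assignments.max()) + 1
    changed = True
    guard = 0
    while changed and guard < 100:
        changed = False
        guard += 1
        for m in np.unique(assignments[assignments >= 0]):
            members = np.flatnonzero(assignments == m)
            if len(members) < size_min:
                assignments[members] = -1
                changed = True
            elif len(members) > size_max:
                sub_k = -(-len(members) // size_max)
                if features is not None:
                    km = KMeans(
                        n_clusters=sub_k,
                        n_init=10,
                        random_state=int(config.seed + m) % 2**31,
                    )
                    sub = km.fit_predict(features[members])
                else:
                    sub = kmedoids(
                        delta[np.ix_(members, members)], sub_k, seed=int(config.seed + m)
                    )
                for s in range(sub_k):
                    assignments[members[sub == s]] = next_id
                    next_id += 1
                changed = True
    assignments = _relabel(assignments)
    if not np.any(assignments >= 0):
        raise ValueError("size control dissolved every cluster; lower size_min")

    out = ClusterPartition(assignments=assignments)
    if features is not None:
        out.centroids = _centroid_matrix(features, assignments)
        cd = (
            squareform(pdist(out.centroids))
            if out.centroids.shape[0] > 1
            else np.zeros((1, 1))
        )
        out.neighbor_sets = _neighbor_sets(cd, config.alpha)
    else:
        _update_medoids(delta, out, config.alpha)
    return out


# ---------------------------------------------------------------------------
# distance-matrix construction


def build_centroid_distances(partition: ClusterPartition) -> np.ndarray:
    """K x K Euclidean distance matrix between cluster centroids."""
    if partition.centroids is None or partition.centroids.shape[0] < 2:
        raise ValueError("need at least 2 clusters with feature-space centroids")
    return squareform(pdist(partition.centroids))


def build_local_distances(
    features: np.ndarray, partition: ClusterPartition, alpha: int
) -> list[dict]:
    """Per-cluster within-cluster and sample-to-neighbor-centroid distances.

    For cluster m, ``delta_self`` is the |A_m| x |A_m| matrix of pairwise
    member distances and ``delta_mutual`` the |A_m| x |xi_m| matrix of
    distances from each member to the alpha nearest neighboring centroids,
    columns ordered as the neighbor set.
    """
    features = np.asarray(features, dtype=float)
    out = []
    for m in range(partition.n_clusters):
        members = partition.members(m)
        fm = features[members]
        delta_self = squareform(pdist(fm)) if len(members) > 1 else np.zeros((1, 1))
        neigh = partition.neighbor_sets[m][: alpha] if partition.neighbor_sets else []
        delta_mutual = (
            cdist(fm, partition.centroids[neigh])
            if len(neigh)
            else np.zeros((len(members), 0))
        )
        out.append(
            {
                "members": members,
                "neighbors": np.asarray(neigh, dtype=int),
                "delta_self": delta_self,
                "delta_mutual": delta_mutual,
            }
        )
    return out


def estimate_distances_from_matrix(
    delta: np.ndarray, partition: ClusterPartition, alpha: int
):
    """Centroid-free analogues of the global/local distance matrices.

    When only a dissimilarity matrix is available there is no feature
    space to average in, so each cluster's medoid stands in for its
    centroid: the global matrix is delta between medoids and the mutual
    matrix holds each member's dissimilarity to the neighbor medoids.
    Under the approximation regime (within-cluster spread much smaller
    than centroid separation) a medoid differs from the centroid by the
    order of the spread, so the substitution preserves the approximation
    argument.

    Returns ``(centroid_delta, locals)`` in the same layout as
    :func:`build_centroid_distances` / :func:`build_local_distances`.
    """
    delta = np.asarray(delta, dtype=float)
    if not np.allclose(delta, delta.T, atol=1e-8):
        raise ValueError("dissimilarity matrix must be symmetric")
    if partition.medoid_ids is None:
        _update_medoids(delta, partition, alpha)
    medoids = partition.medoid_ids
    centroid_delta = delta[np.ix_(medoids, medoids)]
    out = []
    for m in range(partition.n_clusters):
        members = partition.members(m)
        neigh = partition.neighbor_sets[m][:alpha]
        out.append(
            {
                "members": members,
                "neighbors": np.asarray(neigh, dtype=int),
                "delta_self": delta[np.ix_(members, members)],
                "delta_mutual": delta[np.ix_(members, medoids[neigh])]
                if len(neigh)
                else np.zeros((len(members), 0)),
            }
        )
    return centroid_delta, out


def approximate_dissimilarities(
    features: np.ndarray, partition: ClusterPartition, alpha: int
) -> np.ndarray:
    """The dissimilarity matrix the global-local stages actually optimize.

    Within-cluster pairs keep their exact distance; a pair (i in m, j in a
    neighboring cluster n) is replaced by the distance from i to centroid
    n; pairs across non-neighboring clusters inherit the centroid-centroid
    distance.  Comparing this matrix with the exact one quantifies the
    error introduced by the adiabatic approximation.
    """
    features = np.asarray(features, dtype=float)
    n = features.shape[0]
    a = partition.assignments
    if np.any(a < 0):
        raise ValueError("approximation check requires a partition without outliers")
    exact = squareform(pdist(features))
    to_centroid = cdist(features, partition.centroids)
    cd = squareform(pdist(partition.centroids))
    approx = exact.copy()
    neighbor = np.zeros((partition.n_clusters, partition.n_clusters), dtype=bool)
    for m, neigh in enumerate(partition.neighbor_sets):
        neighbor[m, neigh[:alpha]] = True
    for i in range(n):
        m = a[i]
        for j in range(i + 1, n):
            nn = a[j]
            if nn == m:
                continue
            if neighbor[m, nn]:
                approx[i, j] = approx[j, i] = to_centroid[i, nn]
            else:
                approx[i, j] = approx[j, i] = cd[m, nn]
    return approx


# ---------------------------------------------------------------------------
# the full pipeline


def _cluster_seed(master_seed: int, cluster_id: int) -> int:
    """Stable per-cluster seed so serial and concurrent runs agree."""
    ss = np.random.SeedSequence(entropy=master_seed, spawn_key=(cluster_id,))
    return int(ss.generate_state(1)[0] % 2**31)


def _resolve_input(data, kind: str | None):
    if isinstance(data, InputBundle):
        return data.payload, data.kind
    data = np.asarray(data)
    if kind is None:
        raise ValueError("kind must be given for raw arrays")
    if kind == "graph":
        bundle = graph_to_distances(data)
        return bundle.payload, "dissimilarity"
    if kind in ("distances", "dissimilarity"):
        return data.astype(float), "dissimilarity"
    if kind == "features":
        return data.astype(float), "features"
    raise ValueError(f"unknown input kind {kind!r}")


def _fit_local(task, anchors_space, lam, config, prior):
    """One cluster's relax fit; pure function of its arguments."""
    m, local, scale, dim = task
    anchors = HyperbolicPointSet(anchors_space)
    mcount = len(local["members"])
    fitcfg = FitConfig(
        dim=dim,
        seed=_cluster_seed(config.seed, m + 1),
        max_iters=config.max_iters,
        gtol=config.gtol,
        init_scale=config.init_scale,
    )
    rng = np.random.default_rng(fitcfg.seed)
    init = anchors_space[0] + rng.normal(scale=config.init_scale, size=(mcount, dim))
    res = fit_relax(
        local["delta_self"] * scale,
        local["delta_mutual"] * scale,
        anchors,
        lam,
        fitcfg,
        prior,
        init_coords=init,
    )
    return m, res


def run_muhmds(
    data,
    kind: str | None = None,
    config: MultiscaleConfig = MultiscaleConfig(),
    prior: PriorConfig = PriorConfig(),
) -> EmbeddingResult:
    """Embed a dataset into hyperbolic space with the multiscale algorithm.

    Parameters
    ----------
    data : array or InputBundle
        Either an (n, L) feature matrix, an (n, n) symmetric dissimilarity
        matrix, or a graph edge list (shortest-path distances are used).
    kind : {"features", "distances", "graph"}
        Required for raw arrays; InputBundles carry their own kind.
    config : MultiscaleConfig
        Cluster count (or "auto"), anchor neighbor count, size bounds,
        embedding dimension, master seed and the parallelism flag.  The
        flag changes only the execution backend; per-cluster seeds derive
        from the master seed, so results are identical either way.

    Returns
    -------
    EmbeddingResult
        One coordinate row per input sample, in input order, including
        remapped outliers; fitted lambda and sigma; per-stage timings.
        Tiny inputs (n <= 4 or an effective single cluster) fall back to
        the plain full fit.
    """
    payload, kind = _resolve_input(data, kind)
    n = payload.shape[0]
    timings: dict = {}
    dim = config.dim

    features = payload if kind == "features" else None
    delta_full = payload if kind == "dissimilarity" else None

    k = config.resolve_k(n) if n > 4 else 1
    if k < 2 or n <= 4:
        t0 = time.perf_counter()
        delta = delta_full if delta_full is not None else squareform(pdist(features))
        res = fit_bhmds(
            delta,
            FitConfig(
                dim=dim,
                seed=config.seed,
                max_iters=config.max_iters,
                gtol=config.gtol,
                init_scale=config.init_scale,
            ),
            prior,
        )
        if config.center:
            res.points = res.points.centered()
        timings["global"] = time.perf_counter() - t0
        res.timings = timings
        res.provenance.update(
            {
                "cluster_ids": np.zeros(n, dtype=int),
                "outlier_flags": np.zeros(n, dtype=bool),
                "k": 1,
            }
        )
        return res

    # --- clustering + size control
    t0 = time.perf_counter()
    if features is not None:
        part = cluster_samples(features, replace(config, k=k))
        part = enforce_size_bounds(part, config, features=features)
    else:
        part = _cluster_distance_matrix(delta_full, k, config.seed, config.alpha)
        part = enforce_size_bounds(part, config, delta=delta_full)
    timings["cluster"] = time.perf_counter() - t0
    K = part.n_clusters

    # --- distance matrices
    t0 = time.perf_counter()
    if features is not None:
        centroid_delta = build_centroid_distances(part)
        locals_ = build_local_distances(features, part, config.alpha)
        own_mutual = [
            cdist(features[loc["members"]], part.centroids[[m]])
            for m, loc in enumerate(locals_)
        ]
    else:
        centroid_delta, locals_ = estimate_distances_from_matrix(
            delta_full, part, config.alpha
        )
        own_mutual = [
            delta_full[np.ix_(loc["members"], [part.medoid_ids[m]])]
            for m, loc in enumerate(locals_)
        ]
    norm_delta, scale = bhmds.normalize_dissimilarities(centroid_delta)
    timings["distances"] = time.perf_counter() - t0

    # --- global embedding of centroids
    t0 = time.perf_counter()
    global_cfg = FitConfig(
        dim=dim,
        seed=_cluster_seed(config.seed, 0),
        max_iters=config.max_iters,
        gtol=config.gtol,
        init_scale=config.init_scale,
    )
    global_res = fit_bhmds(norm_delta, global_cfg, prior, normalize=False)
    lam = global_res.lam
    Y = global_res.points.spacelike
    timings["global"] = time.perf_counter() - t0

    # --- local relax fits (independent across clusters)
    t0 = time.perf_counter()
    tasks = []
    for m, loc in enumerate(locals_):
        # anchor set: own centroid first, then the alpha nearest neighbors;
        # the proof's local objective optimizes the distance to the own
        # centroid directly, so it must be among the anchors
        mutual = np.hstack([own_mutual[m], loc["delta_mutual"]])
        anchor_ids = np.concatenate([[m], loc["neighbors"]]).astype(int)
        tasks.append(
            (
                (m, {**loc, "delta_mutual": mutual}, scale, dim),
                Y[anchor_ids],
            )
        )

    if config.parallel:
        from joblib import Parallel, delayed

        results = Parallel(n_jobs=-1)(
            delayed(_fit_local)(task, anchors, lam, config, prior)
            for task, anchors in tasks
        )
    else:
        results = [_fit_local(task, anchors, lam, config, prior) for task, anchors in tasks]
    timings["local"] = time.perf_counter() - t0

    # --- integrate in input order
    coords = np.zeros((n, dim))
    sigma = np.full(n, prior.b / (prior.a + 1.0))
    local_loss = 0.0
    for m, res in sorted(results):
        members = locals_[m]["members"]
        coords[members] = res.points.spacelike
        sigma[members] = res.sigma
        local_loss += res.loss

    # --- remap outliers against their nearest embedded samples
    t0 = time.perf_counter()
    outliers = part.outliers
    if len(outliers):
        embedded_mask = part.assignments >= 0
        coords = map_outliers(
            outliers,
            coords,
            embedded_mask,
            features=features,
            delta_full=delta_full,
            scale=scale,
            lam=lam,
            alpha=config.alpha,
            config=config,
            prior=prior,
        )
    timings["remap"] = time.perf_counter() - t0

    if config.center:
        coords = center_points(coords)

    result = EmbeddingResult(
        HyperbolicPointSet(coords),
        lam,
        sigma,
        float(global_res.loss + local_loss),
        scale=scale,
        timings=timings,
        provenance={
            "seed": config.seed,
            "dim": dim,
            "k": K,
            "alpha": config.alpha,
            "cluster_ids": part.assignments.copy(),
            "outlier_flags": part.assignments < 0,
        },
    )
    return result


def map_outliers(
    outliers: np.ndarray,
    coords: np.ndarray,
    embedded_mask: np.ndarray,
    *,
    features: np.ndarray | None = None,
    delta_full: np.ndarray | None = None,
    scale: float,
    lam: float,
    alpha: int,
    config: MultiscaleConfig,
    prior: PriorConfig = PriorConfig(),
) -> np.ndarray:
    """Anchor each excluded sample to its nearest embedded neighbors.

    Every outlier is fitted independently by a relax optimization against
    its alpha nearest already-embedded samples (by input dissimilarity),
    whose coordinates stay untouched.  Returns the coordinate array with
    outlier rows filled in.
    """
    if alpha < 1:
        raise ValueError("alpha must be >= 1")
    embedded_ids = np.flatnonzero(embedded_mask)
    coords = coords.copy()
    dim = coords.shape[1]
    for rank, i in enumerate(outliers):
        if features is not None:
            d = np.linalg.norm(features[embedded_ids] - features[i], axis=1)
        else:
            d = delta_full[i, embedded_ids]
        nearest = embedded_ids[np.argsort(d, kind="stable")[:alpha]]
        if features is not None:
            d_mut = np.linalg.norm(features[nearest] - features[i], axis=1)
        else:
            d_mut = delta_full[i, nearest]
        anchors = HyperbolicPointSet(coords[nearest])
        seed = _cluster_seed(config.seed, -(rank + 1) % 2**31)
        rng = np.random.default_rng(seed)
        fitcfg = FitConfig(
            dim=dim,
            seed=seed,
            max_iters=config.max_iters,
            gtol=config.gtol,
            init_scale=config.init_scale,
        )
        # a lone point against a cone of anchors can have spurious minima;
        # restart from several anchors and keep the lowest loss
        inits = [coords[nearest[0]], coords[nearest].mean(axis=0)]
        inits += [coords[nearest[rng.integers(len(nearest))]] for _ in range(2)]
        best = None
        for init in inits:
            res = fit_relax(
                np.zeros((1, 1)),
                (d_mut * scale)[None, :],
                anchors,
                lam,
                fitcfg,
                prior,
                init_coords=init[None, :] + rng.normal(scale=1e-3, size=(1, dim)),
            )
            if best is None or res.loss < best.loss:
                best = res
        coords[i] = best.points.spacelike[0]
    return coords
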