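"""Seeded synthetic data generators.

These produce every input class the embedding pipeline accepts: ground-truth
hyperbolic point clouds (for recovery experiments), hierarchical branching
"expression" data with known generation depth and branch labels (emulating
differentiation hierarchies such as toggle-switch or myeloid-progenitor
simulations), clustered Gaussian blobs with a controllable spread-to-
separation ratio (probing the regime where centroid-based distance
approximation is valid), and balanced trees as graph edge lists.

All generators are deterministic given (parameters, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import HyperbolicPointSet, pairwise_lorentz_distance

__all__ = [
    "SyntheticDataset",
    "sample_hyperbolic_cloud",
    "generate_branching_data",
    "generate_blobs",
    "generate_balanced_tree",
]


@dataclass
class SyntheticDataset:
    """Generated features (or dissimilarities) with ground-truth labels."""

    features: np.ndarray | None = None
    dissimilarities: np.ndarray | None = None
    labels: dict = field(default_factory=dict)
    params: dict = field(default_factory=dict)

    @property
    def n_samples(self) -> int:
        if self.features is not None:
            return self.features.shape[0]
        return self.dissimilarities.shape[0]


def sample_hyperbolic_cloud(n: int, dim: int, radius_max: float, seed: int = 0):
    """Sample points uniformly w.r.t. hyperbolic volume in a ball of H^D.

    Directions are uniform on the sphere; radii follow the density
    proportional to sinh^(D-1)(r) on [0, radius_max] — the radial law of
    the hyperbolic volume element — drawn by inverse-CDF on a dense grid.

    Returns ``(points, delta)``: a :class:`HyperbolicPointSet` and the
    exact pairwise geodesic distance matrix.
    """
    if radius_max <= 0:
        raise ValueError("radius_max must be positive")
    rng = np.random.default_rng(seed)
    grid = np.linspace(0.0, radius_max, 4096)
    pdf = np.sinh(grid) ** (dim - 1)
    cdf = np.concatenate([[0.0], np.cumsum((pdf[1:] + pdf[:-1]) / 2 * np.diff(grid))])
    cdf /= cdf[-1]
    radii = np.interp(rng.uniform(size=n), cdf, grid)

    dirs = rng.normal(size=(n, dim))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    spacelike = np.sinh(radii)[:, None] * dirs
    points = HyperbolicPointSet(spacelike)
    delta = pairwise_lorentz_distance(spacelike)
    return points, delta


def generate_branching_data(
    n_per_node: int = 20,
    depth: int = 4,
    branching: int = 2,
    step_size: float = 5.0,
    noise: float = 1.0,
    dim_features: int = 50,
    seed: int = 0,
) -> SyntheticDataset:
    """Hierarchical branching expression-like data with known lineage labels.

    Prototype vectors form a tree grown by a Gaussian random walk from a
    root: each child prototype is its parent plus an isotropic step of
    length scale ``step_size``.  Each tree node then emits ``n_per_node``
    samples as prototype + N(0, noise^2) deviations.  Labels record the
    node id, generation depth and, per binary split, an anterior/posterior
    style +-1 code for the first branch decision.

    ``depth`` counts generations below the root (depth=1 and branching=1
    yields a single Gaussian blob).
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    rng = np.random.default_rng(seed)

    protos = [np.zeros(dim_features)]
    node_depth = [0]
    node_branch = [0]  # side of the first split: -1 / +1 (0 for the root)
    parents = [-1]
    frontier = [0]
    for d in range(1, depth + 1):
        new_frontier = []
        for parent in frontier:
            for c in range(branching):
                step = rng.normal(scale=step_size / np.sqrt(dim_features), size=dim_features)
                protos.append(protos[parent] + step)
                node_depth.append(d)
                if node_branch[parent] != 0:
                    side = node_branch[parent]
                elif branching > 1:
                    side = -1 if c < branching / 2 else 1
                else:
                    side = 0
                node_branch.append(side)
                parents.append(parent)
                new_frontier.append(len(protos) - 1)
        frontier = new_frontier

    protos = np.asarray(protos)
    n_nodes = len(protos)
    reps = np.repeat(np.arange(n_nodes), n_per_node)
    features = protos[reps] + rng.normal(scale=noise, size=(len(reps), dim_features))
    labels = {
        "node": reps,
        "generation": np.asarray(node_depth)[reps].astype(float),
        "branch": np.asarray(node_branch)[reps].astype(float),
        "parent": np.asarray(parents),
    }
    return SyntheticDataset(
        features=features,
        labels=labels,
        params={
            "n_per_node": n_per_node,
            "depth": depth,
            "branching": branching,
            "step_size": step_size,
            "noise": noise,
            "seed": seed,
        },
    )


def generate_blobs(
    k_true: int,
    n_per: int,
    spread: float,
    separation: float,
    dim: int = 10,
    seed: int = 0,
) -> SyntheticDataset:
    """Isotropic Gaussian blobs with controlled spread/separation ratio.

    Centers are drawn and then rescaled so the minimum pairwise center
    distance equals ``separation``; each blob emits ``n_per`` samples with
    standard deviation ``spread``.  The ratio s/S = spread/separation is
    recorded — it is the small parameter of the centroid-approximation
    argument (within-cluster displacements much smaller than centroid
    separations).
    """
    if spread <= 0 or separation <= 0:
        raise ValueError("spread and separation must be positive")
    rng = np.random.default_rng(seed)
    centers = rng.normal(size=(k_true, dim))
    diff = centers[:, None, :] - centers[None, :, :]
    dist = np.linalg.norm(diff, axis=-1)
    np.fill_diagonal(dist, np.inf)
    centers *= separation / dist.min()
    features = np.repeat(centers, n_per, axis=0) + rng.normal(
        scale=spread, size=(k_true * n_per, dim)
    )
    labels = {"cluster": np.repeat(np.arange(k_true), n_per)}
    return SyntheticDataset(
        features=features,
        labels=labels,
        params={
            "k_true": k_true,
            "n_per": n_per,
            "spread": spread,
            "separation": separation,
            "ratio": spread / separation,
            "seed": seed,
        },
    )


def generate_balanced_tree(depth: int, branching: int) -> np.ndarray:
    """Edge list of a fully balanced rooted tree.

    Node 0 is the root; every internal node has ``branching`` children and
    each node is connected only to its direct ancestor.  The node count is
    (b^(d+1) - 1)/(b - 1).

    Returns an (n_edges, 2) integer array.
    """
    if depth < 1 or branching < 2:
        raise ValueError("depth >= 1 and branching >= 2 required")
    edges = []
    frontier = [0]
    next_id = 1
    for _ in range(depth):
        new_frontier = []
        for parent in frontier:
            for _ in range(branching):
                edges.append((parent, next_id))
                new_frontier.append(next_id)
                next_id += 1
        frontier = new_frontier
    return np.asarray(edges, dtype=int)
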