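"""Bayesian hyperbolic multidimensional scaling (MAP estimation).

The generative model assumes observed dissimilarities arise from geodesic
distances in hyperbolic space, divided by a global scale factor lambda and
corrupted by Gaussian noise:

    delta_ij = d_ij / lambda + eps_ij,   eps_ij ~ N(0, sigma_ij^2),

with per-point uncertainties combined as sigma_ij^2 = sigma_i^2 + sigma_j^2
(springs in series).  Because coordinates live on the unit-curvature
hyperboloid, fitting lambda is equivalent to fitting the curvature scale of
the space.  Dissimilarities are normalized so the largest entry is 2, which
makes lambda interpretable as the radius of the embedded point cloud.

With a normal prior on lambda (strength rescaled by the number of pairs so
it does not wash out at large n), an inverse-gamma prior on each sigma_i and
a flat prior on the coordinates, the negative log-posterior is

    L = 1/2 sum_{i<j} [ (d_ij/lam - delta_ij)^2 / (s_i^2 + s_j^2)
                        + ln(s_i^2 + s_j^2) ]
        + n(n-1)/(4 sigma_lam^2) * lam^2
        + sum_i [ (a+1) ln s_i + b / s_i ].

MAP fitting maximizes this posterior with a limited-memory quasi-Newton
optimizer over the spacelike coordinates and the logs of lambda and the
sigma_i (log-reparameterization enforces positivity).  The "relax" variant
optimizes a set of new points against frozen anchor positions with lambda
held fixed — the workhorse of the multiscale local-embedding stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .geometry import HyperbolicPointSet, timelike

__all__ = [
    "PriorConfig",
    "FitConfig",
    "EmbeddingResult",
    "normalize_dissimilarities",
    "neg_log_posterior",
    "neg_log_posterior_grad",
    "fit_bhmds",
    "fit_relax",
]

_SIGMA_FLOOR = 1e-4


@dataclass(frozen=True)
class PriorConfig:
    """Hyperparameters of the priors on lambda and the sigma_i.

    ``sigma_lambda`` is the scale of the normal prior on lambda; ``a`` and
    ``b`` are the shape and scale of the inverse-gamma prior on each
    sigma_i (mode b/(a+1)).
    """

    sigma_lambda: float = 10.0
    a: float = 2.0
    b: float = 0.5

    def __post_init__(self):
        if self.sigma_lambda <= 0 or self.a <= 0 or self.b <= 0:
            raise ValueError("prior hyperparameters must be positive")


@dataclass(frozen=True)
class FitConfig:
    """Optimizer controls for a single MAP fit."""

    dim: int = 3
    max_iters: int = 2000
    gtol: float = 1e-6
    seed: int = 0
    init_scale: float = 0.1

    def __post_init__(self):
        if self.dim < 2:
            raise ValueError("embedding dimension must be >= 2")
        if self.gtol <= 0 or self.init_scale <= 0:
            raise ValueError("tolerances must be positive")


@dataclass
class EmbeddingResult:
    """Output of a MAP fit: coordinates plus fitted scale and uncertainties.

    ``scale`` is the factor that was applied to the input dissimilarities
    during max-entry-2 normalization; estimated dissimilarities in the
    original units are ``d_ij / (lam * scale)``.
    """

    points: HyperbolicPointSet
    lam: float
    sigma: np.ndarray
    loss: float
    scale: float = 1.0
    n_iter: int = 0
    timings: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    @property
    def coords(self) -> np.ndarray:
        return self.points.spacelike

    def embedded_distances(self) -> np.ndarray:
        """Pairwise hyperbolic distances of the embedded points."""
        return self.points.distance_matrix()

    def estimated_dissimilarities(self) -> np.ndarray:
        """Model-implied dissimilarities d_ij/(lam*scale), original units."""
        return self.embedded_distances() / (self.lam * self.scale)


def normalize_dissimilarities(delta: np.ndarray, *, check: bool = True):
    """Rescale a dissimilarity matrix so the maximum entry equals 2.

    Returns ``(normalized, scale)`` where ``normalized = delta * scale``.
    Ratios between entries are preserved; the scale factor lets results be
    reported back in the original units.
    """
    delta = np.asarray(delta, dtype=float)
    if check:
        if delta.ndim != 2 or delta.shape[0] != delta.shape[1]:
            raise ValueError("dissimilarity matrix must be square")
        if not np.allclose(delta, delta.T, atol=1e-8):
            raise ValueError("dissimilarity matrix must be symmetric")
        if np.any(delta < 0):
            raise ValueError("dissimilarities must be nonnegative")
        if np.any(np.abs(np.diag(delta)) > 1e-8):
            raise ValueError("dissimilarity matrix must have zero diagonal")
    m = delta.max()
    if m <= 0:
        raise ValueError("degenerate dissimilarity matrix: all entries zero")
    scale = 2.0 / m
    return delta * scale, scale


def _pair_distances(coords: np.ndarray):
    """Pairwise distances plus the quantities the gradient reuses."""
    x0 = timelike(coords)
    inner = np.outer(x0, x0) - coords @ coords.T
    np.clip(inner, 1.0, None, out=inner)
    d = np.arccosh(inner)
    return d, inner, x0


def neg_log_posterior(
    coords: np.ndarray,
    lam: float,
    sigma: np.ndarray,
    delta: np.ndarray,
    prior: PriorConfig = PriorConfig(),
) -> float:
    """Negative log-posterior L for coordinates, scale and uncertainties.

    ``delta`` is assumed normalized (max entry 2); ``coords`` holds the
    (n, D) spacelike parameters.
    """
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    sigma = np.asarray(sigma, dtype=float)
    delta = np.asarray(delta, dtype=float)
    n = coords.shape[0]
    if delta.shape != (n, n):
        raise ValueError(f"delta shape {delta.shape} does not match {n} coordinates")
    if sigma.shape != (n,):
        raise ValueError("sigma must have one entry per point")

    loss = n * (n - 1) / (4.0 * prior.sigma_lambda**2) * lam**2
    loss += np.sum((prior.a + 1.0) * np.log(sigma) + prior.b / sigma)
    if n >= 2:
        d, _, _ = _pair_distances(coords)
        iu = np.triu_indices(n, k=1)
        r = d[iu] / lam - delta[iu]
        s2 = sigma[:, None] ** 2 + sigma[None, :] ** 2
        loss += 0.5 * np.sum(r * r / s2[iu] + np.log(s2[iu]))
    return float(loss)


def neg_log_posterior_grad(coords, lam, sigma, delta, prior=PriorConfig()):
    """Analytic gradient of ``neg_log_posterior``.

    Returns ``(g_coords, g_lam, g_sigma)`` — derivatives with respect to
    the spacelike coordinates, lambda and the sigma_i (not their logs).
    """
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    sigma = np.asarray(sigma, dtype=float)
    n, _ = coords.shape
    d, inner, x0 = _pair_distances(coords)
    s2 = sigma[:, None] ** 2 + sigma[None, :] ** 2
    r = d / lam - delta
    np.fill_diagonal(r, 0.0)

    # dL/dd_ij = r_ij / (lam * s2_ij); chain through d = arccosh(inner)
    W = r / (lam * s2)
    sinh_d = np.sqrt(np.maximum(inner * inner - 1.0, 1e-24))
    C = W / sinh_d
    np.fill_diagonal(C, 0.0)
    g_coords = (C @ x0)[:, None] * coords / x0[:, None] - C @ coords

    iu = np.triu_indices(n, k=1)
    g_lam = float(-np.sum(r[iu] * d[iu] / s2[iu]) / lam**2)
    g_lam += n * (n - 1) / (2.0 * prior.sigma_lambda**2) * lam

    # the axis=1 sum includes the j=i diagonal (r_ii=0, s2_ii=2 sigma_i^2)
    # whose spurious contribution sigma_i/(2 sigma_i^2) is subtracted
    rr_s2 = (1.0 - (r * r) / s2) / s2  # grouped to avoid overflowing s2^2
    g_sigma = sigma * (np.sum(rr_s2, axis=1) - 0.5 / sigma**2)
    g_sigma += (prior.a + 1.0) / sigma - prior.b / sigma**2
    return g_coords, g_lam, g_sigma


def _pack(coords, log_lam, log_sigma):
    return np.concatenate([coords.ravel(), [log_lam], log_sigma])


def _fit_loop(fun_grad, z0, config, ftol=1e-12):
    # positivity of lambda and sigma is enforced by the log/softplus-style
    # reparameterization, so the quasi-Newton step stays unconstrained
    res = minimize(
        fun_grad,
        z0,
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": config.max_iters, "gtol": config.gtol, "ftol": ftol},
    )
    return res


def _sigma_of(z):
    """sigma = floor + exp(z): keeps ln(sigma_i^2 + sigma_j^2) finite."""
    return _SIGMA_FLOOR + np.exp(z)


def fit_bhmds(
    delta: np.ndarray,
    config: FitConfig = FitConfig(),
    prior: PriorConfig = PriorConfig(),
    *,
    normalize: bool = True,
) -> EmbeddingResult:
    """MAP fit of the full Bayesian hyperbolic MDS model.

    Parameters
    ----------
    delta : (n, n) array
        Symmetric nonnegative dissimilarities with zero diagonal.  Unless
        ``normalize=False`` they are rescaled so the max entry is 2.
    config, prior
        Optimizer controls and prior hyperparameters.

    Returns
    -------
    EmbeddingResult with points on the hyperboloid, fitted lambda and
    per-point sigma_i, the final loss and the normalization scale.
    """
    delta = np.asarray(delta, dtype=float)
    n = delta.shape[0]
    if n == 0:
        raise ValueError("cannot embed an empty dissimilarity matrix")
    if n == 1:
        sigma0 = np.array([prior.b / (prior.a + 1.0)])
        pts = HyperbolicPointSet(np.zeros((1, config.dim)))
        loss = neg_log_posterior(pts.spacelike, 1.0, sigma0, np.zeros((1, 1)), prior)
        return EmbeddingResult(pts, 1.0, sigma0, loss, scale=1.0)

    scale = 1.0
    if normalize:
        delta, scale = normalize_dissimilarities(delta)

    D = config.dim
    rng = np.random.default_rng(config.seed)
    coords0 = rng.normal(scale=config.init_scale, size=(n, D))
    sigma_mode = prior.b / (prior.a + 1.0)

    iu = np.triu_indices(n, k=1)
    pair_prior = n * (n - 1) / (4.0 * prior.sigma_lambda**2)

    def make_fun_grad(sigma_fixed=None):
        def fun_grad(z):
            coords = z[: n * D].reshape(n, D)
            lam = np.exp(z[n * D])
            sigma = sigma_fixed if sigma_fixed is not None else _sigma_of(z[n * D + 1 :])
            d, inner, x0 = _pair_distances(coords)
            s2 = sigma[:, None] ** 2 + sigma[None, :] ** 2
            r = d / lam - delta
            np.fill_diagonal(r, 0.0)
            loss = 0.5 * np.sum(r[iu] ** 2 / s2[iu] + np.log(s2[iu]))
            loss += pair_prior * lam**2
            loss += np.sum((prior.a + 1.0) * np.log(sigma) + prior.b / sigma)

            W = r / (lam * s2)
            C = W / np.sqrt(np.maximum(inner * inner - 1.0, 1e-24))
            np.fill_diagonal(C, 0.0)
            g_coords = (C @ x0)[:, None] * coords / x0[:, None] - C @ coords
            g_lam = -np.sum(r[iu] * d[iu] / s2[iu]) / lam**2 + 2.0 * pair_prior * lam
            if sigma_fixed is not None:
                return loss, np.concatenate([g_coords.ravel(), [g_lam * lam]])
            rr_s2 = (1.0 - (r * r) / s2) / s2
            g_sigma = sigma * (np.sum(rr_s2, axis=1) - 0.5 / sigma**2)
            g_sigma += (prior.a + 1.0) / sigma - prior.b / sigma**2
            g = np.concatenate(
                [g_coords.ravel(), [g_lam * lam], g_sigma * (sigma - _SIGMA_FLOOR)]
            )
            return loss, g

        return fun_grad

    # Phase 1 (warm-up): coordinates and lambda only, sigma frozen at the
    # prior mode.  Large early residuals would otherwise inflate the
    # sigma_i, damping the coordinate gradients by 1/sigma^2 and stalling
    # the expansion of the point cloud from its small random start.
    z0 = np.concatenate([coords0.ravel(), [0.0]])
    res1 = _fit_loop(make_fun_grad(np.full(n, sigma_mode)), z0, config)

    # Phase 2: joint refinement of coordinates, lambda and sigma.
    z1 = np.concatenate([res1.x, np.full(n, np.log(sigma_mode - _SIGMA_FLOOR))])
    res = _fit_loop(make_fun_grad(), z1, config, ftol=1e-9)

    coords = res.x[: n * D].reshape(n, D)
    lam = float(np.exp(res.x[n * D]))
    sigma = _sigma_of(res.x[n * D + 1 :])
    return EmbeddingResult(
        HyperbolicPointSet(coords),
        lam,
        sigma,
        float(res.fun),
        scale=scale,
        n_iter=int(res1.nit + res.nit),
        provenance={"seed": config.seed, "dim": config.dim},
    )


def fit_relax(
    delta_self: np.ndarray,
    delta_mutual: np.ndarray,
    anchors: HyperbolicPointSet,
    lam: float,
    config: FitConfig = FitConfig(),
    prior: PriorConfig = PriorConfig(),
    *,
    init_coords: np.ndarray | None = None,
) -> EmbeddingResult:
    """Embed new points against frozen anchors (the "relax" optimization).

    Only the new points' coordinates and uncertainties are optimized; the
    anchor coordinates and the scale lambda — inherited from the global
    stage so local and global distances share one metric — stay fixed.  The
    residual sum splits into within-new pairs (weighted by
    sigma_i^2 + sigma_j^2) and new-to-anchor terms; anchors are treated as
    noiseless, so anchor terms are weighted by sigma_i^2 alone.

    Parameters
    ----------
    delta_self : (m, m) array
        Dissimilarities among the new points (normalized scale).  May be a
        1x1 zero matrix for a single point.
    delta_mutual : (m, p) array
        Dissimilarities from each new point to each anchor, column order
        matching ``anchors``.
    anchors : HyperbolicPointSet
        Fixed, previously embedded positions.
    lam : float
        Frozen scale from the global fit.
    init_coords : optional (m, D) array
        Starting spacelike coordinates (e.g. near the parent centroid).
    """
    delta_self = np.atleast_2d(np.asarray(delta_self, dtype=float))
    delta_mutual = np.atleast_2d(np.asarray(delta_mutual, dtype=float))
    m = delta_self.shape[0]
    p = anchors.n_points if delta_mutual.size else 0
    if delta_mutual.size and delta_mutual.shape != (m, p):
        raise ValueError(
            f"delta_mutual shape {delta_mutual.shape} does not match "
            f"{m} new points x {p} anchors"
        )
    if p == 0 and m <= 1:
        raise ValueError("underdetermined: no anchors and at most one new point")

    D = config.dim
    A = anchors.spacelike
    a0 = timelike(A) if p else np.zeros(0)
    rng = np.random.default_rng(config.seed)
    if init_coords is not None:
        coords0 = np.array(init_coords, dtype=float).reshape(m, D)
    else:
        coords0 = rng.normal(scale=config.init_scale, size=(m, D))
    log_sigma0 = np.full(m, np.log(prior.b / (prior.a + 1.0) - _SIGMA_FLOOR))
    z0 = np.concatenate([coords0.ravel(), log_sigma0])

    iu = np.triu_indices(m, k=1)

    def fun_grad(z):
        coords = z[: m * D].reshape(m, D)
        sigma = _sigma_of(z[m * D :])
        x0 = timelike(coords)
        loss = 0.0
        g_coords = np.zeros((m, D))
        g_sigma_raw = np.zeros(m)

        if m >= 2:
            inner = np.outer(x0, x0) - coords @ coords.T
            np.clip(inner, 1.0, None, out=inner)
            d = np.arccosh(inner)
            s2 = sigma[:, None] ** 2 + sigma[None, :] ** 2
            r = d / lam - delta_self
            np.fill_diagonal(r, 0.0)
            loss += 0.5 * np.sum(r[iu] ** 2 / s2[iu] + np.log(s2[iu]))
            C = r / (lam * s2) / np.sqrt(np.maximum(inner * inner - 1.0, 1e-24))
            np.fill_diagonal(C, 0.0)
            g_coords += (C @ x0)[:, None] * coords / x0[:, None] - C @ coords
            rr_s2 = (1.0 - (r * r) / s2) / s2
            g_sigma_raw += sigma * (np.sum(rr_s2, axis=1) - 0.5 / sigma**2)

        if p:
            inner_a = np.outer(x0, a0) - coords @ A.T
            np.clip(inner_a, 1.0, None, out=inner_a)
            da = np.arccosh(inner_a)
            sa2 = (sigma**2)[:, None]
            ra = da / lam - delta_mutual
            loss += 0.5 * np.sum(ra * ra / sa2 + np.log(sa2))
            Ca = ra / (lam * sa2) / np.sqrt(np.maximum(inner_a * inner_a - 1.0, 1e-24))
            g_coords += (Ca @ a0)[:, None] * coords / x0[:, None] - Ca @ A
            # each anchor term 1/2(ra^2/s^2 + ln s^2) with s^2 = sigma_i^2
            # contributes sigma_i * (1/s^2 - ra^2/s^4)
            g_sigma_raw += sigma * np.sum((1.0 - (ra * ra) / sa2) / sa2, axis=1)

        loss += np.sum((prior.a + 1.0) * np.log(sigma) + prior.b / sigma)
        g_sigma = g_sigma_raw + (prior.a + 1.0) / sigma - prior.b / sigma**2
        g = np.concatenate([g_coords.ravel(), g_sigma * (sigma - _SIGMA_FLOOR)])
        return loss, g

    res = _fit_loop(fun_grad, z0, config)
    coords = res.x[: m * D].reshape(m, D)
    sigma = _sigma_of(res.x[m * D :])
    return EmbeddingResult(
        HyperbolicPointSet(coords),
        lam,
        sigma,
        float(res.fun),
        n_iter=int(res.nit),
        provenance={"seed": config.seed, "dim": config.dim, "relax": True},
    )
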