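"""Hyperbolic geometry kernel: Lorentz (hyperboloid) and Poincare ball models.

D-dimensional hyperbolic space of curvature K = -1 is represented as the
future-facing sheet of a two-sheeted hyperboloid in (D+1)-dimensional
Minkowski space: the set of points x with

    <x, x>_L = x_0^2 - x_1^2 - ... - x_D^2 = 1,   x_0 >= 1,

where ``<.,.>_L`` is the Minkowski bilinear form with metric signature
(+, -, ..., -).  Only the D spacelike components are free parameters; the
timelike component is always derived from the constraint, which keeps every
point exactly on the sheet and makes gradient-based optimization stable.

Arrays of points are stored row-wise.  "Spacelike" arrays have shape (n, D);
"ambient" arrays have shape (n, D+1) with the timelike coordinate first.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "lift",
    "timelike",
    "minkowski_inner",
    "lorentz_distance",
    "pairwise_lorentz_distance",
    "cross_lorentz_distance",
    "to_poincare",
    "from_poincare",
    "poincare_distance",
    "mobius_add",
    "log_map_origin",
    "center_points",
    "HyperbolicPointSet",
]

# Ball norms are clamped strictly inside the unit ball and Minkowski inner
# products clamped to >= 1 before arccosh/arctanh, which are undefined under
# rounding error at the boundary of their domains.
_BALL_EPS = 1e-12
_ONSHEET_TOL = 1e-6


class GeometryError(ValueError):
    """Raised when inputs violate the hyperbolic model's domain."""


def timelike(spacelike: np.ndarray) -> np.ndarray:
    """Timelike coordinate x_0 = sqrt(1 + |x|^2) for spacelike rows."""
    spacelike = np.asarray(spacelike, dtype=float)
    return np.sqrt(1.0 + np.sum(spacelike * spacelike, axis=-1))


def lift(spacelike: np.ndarray) -> np.ndarray:
    """Lift spacelike coordinates onto the hyperboloid sheet.

    Parameters
    ----------
    spacelike : (..., D) array
        Free coordinates.

    Returns
    -------
    (..., D+1) array with the derived timelike coordinate prepended, so
    that the constraint ``<x, x>_L = 1`` holds exactly by construction.
    """
    spacelike = np.atleast_1d(np.asarray(spacelike, dtype=float))
    if not np.all(np.isfinite(spacelike)):
        raise GeometryError("spacelike coordinates must be finite")
    x0 = timelike(spacelike)
    return np.concatenate([x0[..., None], spacelike], axis=-1)


def minkowski_inner(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Minkowski inner product <x, y>_L = x_0 y_0 - vec(x) . vec(y)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    return x[..., 0] * y[..., 0] - np.sum(x[..., 1:] * y[..., 1:], axis=-1)


def _check_on_sheet(x: np.ndarray) -> None:
    q = minkowski_inner(x, x)
    if np.any(np.abs(q - 1.0) > _ONSHEET_TOL):
        raise GeometryError("point does not satisfy the hyperboloid constraint")


def lorentz_distance(x: np.ndarray, y: np.ndarray, *, validate: bool = True) -> np.ndarray:
    """Geodesic distance d(x, y) = arccosh(<x, y>_L) between ambient points.

    The inner product is clamped to >= 1 to absorb rounding; a value far
    below 1 indicates points off the sheet and raises ``GeometryError``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    inner = minkowski_inner(x, y)
    if validate:
        _check_on_sheet(x)
        _check_on_sheet(y)
        if np.any(inner < 1.0 - _ONSHEET_TOL):
            raise GeometryError("Minkowski inner product < 1: points off the sheet")
    return np.arccosh(np.maximum(inner, 1.0))


def pairwise_lorentz_distance(spacelike: np.ndarray) -> np.ndarray:
    """All-pairs hyperbolic distance matrix from (n, D) spacelike rows."""
    X = np.atleast_2d(np.asarray(spacelike, dtype=float))
    x0 = timelike(X)
    inner = np.outer(x0, x0) - X @ X.T
    d = np.arccosh(np.maximum(inner, 1.0))
    np.fill_diagonal(d, 0.0)  # <x,x>_L = 1 only up to rounding
    return d


def cross_lorentz_distance(spacelike_a: np.ndarray, spacelike_b: np.ndarray) -> np.ndarray:
    """(n, m) distance matrix between two spacelike point sets."""
    A = np.atleast_2d(np.asarray(spacelike_a, dtype=float))
    B = np.atleast_2d(np.asarray(spacelike_b, dtype=float))
    inner = np.outer(timelike(A), timelike(B)) - A @ B.T
    return np.arccosh(np.maximum(inner, 1.0))


def to_poincare(x: np.ndarray) -> np.ndarray:
    """Stereographic projection of ambient hyperboloid points to the ball.

    u = vec(x) / (1 + x_0) maps the sheet bijectively onto the open unit
    ball; the origin of the sheet maps to the ball origin.
    """
    x = np.asarray(x, dtype=float)
    return x[..., 1:] / (1.0 + x[..., 0])[..., None]


def from_poincare(u: np.ndarray) -> np.ndarray:
    """Inverse stereographic projection; returns ambient coordinates."""
    u = np.atleast_1d(np.asarray(u, dtype=float))
    sq = np.sum(u * u, axis=-1)
    if np.any(sq >= 1.0):
        raise GeometryError("Poincare coordinates must lie strictly inside the unit ball")
    denom = (1.0 - sq)[..., None]
    x0 = (1.0 + sq)[..., None] / denom
    vec = 2.0 * u / denom
    return np.concatenate([x0, vec], axis=-1)


def poincare_distance(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Hyperbolic distance in the Poincare ball model.

    d_H(u, v) = arccosh(1 + 2|u - v|^2 / ((1 - |u|^2)(1 - |v|^2))).
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    uu = np.sum(u * u, axis=-1)
    vv = np.sum(v * v, axis=-1)
    if np.any(uu >= 1.0) or np.any(vv >= 1.0):
        raise GeometryError("Poincare coordinates must lie strictly inside the unit ball")
    diff = np.sum((u - v) ** 2, axis=-1)
    denom = np.maximum((1.0 - uu) * (1.0 - vv), _BALL_EPS)
    return np.arccosh(np.maximum(1.0 + 2.0 * diff / denom, 1.0))


def mobius_add(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Mobius addition u (+) v, the ball model's vector addition.

    u (+) v = ((1 + 2 u.v + |v|^2) u + (1 - |u|^2) v)
              / (1 + 2 u.v + |u|^2 |v|^2)
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    uu = np.sum(u * u, axis=-1, keepdims=True)
    vv = np.sum(v * v, axis=-1, keepdims=True)
    if np.any(uu >= 1.0) or np.any(vv >= 1.0):
        raise GeometryError("Poincare coordinates must lie strictly inside the unit ball")
    uv = np.sum(u * v, axis=-1, keepdims=True)
    num = (1.0 + 2.0 * uv + vv) * u + (1.0 - uu) * v
    den = 1.0 + 2.0 * uv + uu * vv
    out = num / den
    # exact cancellation u (+) (-u) can overshoot the ball by rounding
    norm = np.sqrt(np.sum(out * out, axis=-1, keepdims=True))
    scale = np.minimum(1.0, (1.0 - _BALL_EPS) / np.maximum(norm, _BALL_EPS))
    return out * np.where(norm >= 1.0, scale, 1.0)


def log_map_origin(x: np.ndarray) -> np.ndarray:
    """Logarithmic map at the origin: hyperboloid point -> tangent vector.

    For base point p = (1, 0, ..., 0),

        log_p(x) = arccosh(x_0) * (x - x_0 p) / |vec(x)|,

    restricted to its spacelike part, so the output is a D-vector whose
    Euclidean norm equals the geodesic distance from the origin to x.  The
    origin itself maps to the zero vector (the 0/0 limit).
    """
    x = np.asarray(x, dtype=float)
    vec = x[..., 1:]
    r = np.arccosh(np.maximum(x[..., 0], 1.0))
    norm = np.sqrt(np.sum(vec * vec, axis=-1))
    scale = np.where(norm > 0.0, r / np.where(norm > 0.0, norm, 1.0), 0.0)
    return vec * scale[..., None]


def center_points(spacelike: np.ndarray) -> np.ndarray:
    """Translate a point set so its Lorentzian mean sits at the origin.

    The hyperbolic distance matrix is invariant under Lorentz boosts, so a
    fitted configuration is only defined up to isometry.  Radius-based
    analyses (pseudotime, tangent projections) need a canonical origin;
    this gauge fix boosts the normalized Euclidean mean of the ambient
    coordinates — a standard proxy for the Frechet mean — to the origin.

    Returns the boosted spacelike coordinates; all pairwise distances are
    preserved to machine precision.
    """
    X = np.atleast_2d(np.asarray(spacelike, dtype=float))
    amb = lift(X)
    mu = amb.mean(axis=0)
    q = minkowski_inner(mu, mu)
    if q <= 0:
        return X.copy()
    b = mu / np.sqrt(q)
    b0, bv = b[0], b[1:]
    # inverse Lorentz boost: maps b to (1, 0, ..., 0)
    D = X.shape[1]
    boost = np.empty((D + 1, D + 1))
    boost[0, 0] = b0
    boost[0, 1:] = -bv
    boost[1:, 0] = -bv
    boost[1:, 1:] = np.eye(D) + np.outer(bv, bv) / (1.0 + b0)
    out = amb @ boost.T
    return out[:, 1:]


class HyperbolicPointSet:
    """n points on the unit hyperboloid, stored by their spacelike parts.

    The timelike coordinate is always derived, never stored, so every point
    satisfies the sheet constraint by construction.
    """

    def __init__(self, spacelike: np.ndarray):
        spacelike = np.atleast_2d(np.asarray(spacelike, dtype=float))
        if not np.all(np.isfinite(spacelike)):
            raise GeometryError("spacelike coordinates must be finite")
        self.spacelike = spacelike

    @property
    def n_points(self) -> int:
        return self.spacelike.shape[0]

    @property
    def dim(self) -> int:
        return self.spacelike.shape[1]

    @property
    def ambient(self) -> np.ndarray:
        """(n, D+1) ambient coordinates with x_0 first."""
        return lift(self.spacelike)

    def radii(self) -> np.ndarray:
        """Hyperbolic distance of each point to the origin."""
        return np.arccosh(timelike(self.spacelike))

    def distance_matrix(self) -> np.ndarray:
        return pairwise_lorentz_distance(self.spacelike)

    def to_poincare(self) -> np.ndarray:
        return to_poincare(self.ambient)

    def centered(self) -> "HyperbolicPointSet":
        return HyperbolicPointSet(center_points(self.spacelike))

    def __len__(self) -> int:
        return self.n_points

    def __repr__(self) -> str:
        return f"HyperbolicPointSet(n={self.n_points}, dim={self.dim})"
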