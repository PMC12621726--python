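"""Embedding-quality metrics: co-ranking Q curves, Shepard correlation and
distortion rate.

The co-ranking family is scale-independent: it compares only the *ranks* of
pairwise distances before and after embedding.  Q_NX(K) is the fraction of
each point's K nearest neighbors that are preserved among its K nearest
embedded neighbors, averaged over points.  The curve is split at the scale
K* that maximizes the chance-corrected curve (the local continuity
meta-criterion, LCMC); the mean of Q_NX below the split is Q_local, above
it Q_global.

The Shepard correlation is the Pearson correlation between original and
embedded pairwise distances, and the distortion rate is the mean relative
absolute error |d_emb - d_orig| / d_orig over unordered pairs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "QualityReport",
    "coranking_matrix",
    "q_curve",
    "q_curve_and_split",
    "shepard_correlation",
    "distortion_rate",
    "quality_report",
]


@dataclass(frozen=True)
class QualityReport:
    """Quality summary for one embedding."""

    q_local: float
    q_global: float
    shepard_r: float
    distortion: float

    def __post_init__(self):
        for name in ("q_local", "q_global"):
            v = getattr(self, name)
            if not (-1e-9 <= v <= 1 + 1e-9):
                raise ValueError(f"{name}={v} out of [0, 1]")
        if not (-1 - 1e-9 <= self.shepard_r <= 1 + 1e-9):
            raise ValueError(f"shepard_r={self.shepard_r} out of [-1, 1]")
        if self.distortion < 0:
            raise ValueError("distortion must be nonnegative")


def _rank_matrix(d: np.ndarray) -> np.ndarray:
    """Per-row neighbor ranks 1..n-1 excluding self; ties broken by index."""
    n = d.shape[0]
    d = np.array(d, dtype=float)
    np.fill_diagonal(d, np.inf)  # self is never a neighbor
    order = np.argsort(d, axis=1, kind="stable")[:, : n - 1]
    ranks = np.zeros((n, n), dtype=int)
    rows = np.repeat(np.arange(n), n - 1)
    ranks[rows, order.ravel()] = np.tile(np.arange(1, n), n)
    return ranks


def coranking_matrix(d_high: np.ndarray, d_low: np.ndarray) -> np.ndarray:
    """Joint histogram of neighbor ranks in the two spaces.

    Entry (r, s) (1-based ranks; 0-based array indices r-1, s-1) counts
    ordered point pairs whose high-space neighbor rank is r and low-space
    rank is s.  The result is (n-1) x (n-1) with every row and column sum
    equal to n.
    """
    d_high = np.asarray(d_high, dtype=float)
    d_low = np.asarray(d_low, dtype=float)
    if d_high.shape != d_low.shape:
        raise ValueError("distance matrices must have matching shapes")
    n = d_high.shape[0]
    if n < 3:
        raise ValueError("co-ranking needs at least 3 points")
    rh = _rank_matrix(d_high)
    rl = _rank_matrix(d_low)
    mask = ~np.eye(n, dtype=bool)
    Q = np.zeros((n - 1, n - 1), dtype=int)
    np.add.at(Q, (rh[mask] - 1, rl[mask] - 1), 1)
    return Q


def q_curve(Q: np.ndarray) -> np.ndarray:
    """Q_NX(K) for K = 1..n-2: normalized mass of the KxK upper-left block."""
    n = Q.shape[0] + 1
    block = np.cumsum(np.cumsum(Q, axis=0), axis=1)
    K = np.arange(1, n - 1)
    return block[K - 1, K - 1] / (K * n)


def q_curve_and_split(Q: np.ndarray):
    """Split the Q_NX curve into local and global averages.

    The split scale K* maximizes the LCMC-adjusted curve
    Q_NX(K) - K/(n-1).  Returns ``(q_local, q_global)``: the means of
    Q_NX over K <= K* and K > K*.
    """
    n = Q.shape[0] + 1
    if n < 4:
        raise ValueError("Q split undefined for fewer than 4 points")
    qnx = q_curve(Q)
    K = np.arange(1, n - 1)
    lcmc = qnx - K / (n - 1)
    k_star = int(K[np.argmax(lcmc)])
    q_local = float(np.mean(qnx[K <= k_star]))
    q_global = float(np.mean(qnx[K > k_star])) if np.any(K > k_star) else float("nan")
    return q_local, q_global


def shepard_correlation(d_high: np.ndarray, d_low: np.ndarray) -> float:
    """Pearson correlation of the strict upper triangles of two matrices."""
    d_high = np.asarray(d_high, dtype=float)
    d_low = np.asarray(d_low, dtype=float)
    if d_high.shape != d_low.shape:
        raise ValueError("distance matrices must have matching shapes")
    iu = np.triu_indices(d_high.shape[0], k=1)
    a, b = d_high[iu], d_low[iu]
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("Shepard correlation undefined for constant distances")
    return float(np.corrcoef(a, b)[0, 1])


def distortion_rate(d_orig: np.ndarray, d_embedded: np.ndarray) -> float:
    """Mean relative absolute distance error over unordered pairs.

    (1 / C(n,2)) * sum_{x != y} |d_emb(x,y) - d_orig(x,y)| / d_orig(x,y).
    Zero off-diagonal original distances make the formula undefined and
    raise an error.
    """
    d_orig = np.asarray(d_orig, dtype=float)
    d_embedded = np.asarray(d_embedded, dtype=float)
    if d_orig.shape != d_embedded.shape:
        raise ValueError("distance matrices must have matching shapes")
    iu = np.triu_indices(d_orig.shape[0], k=1)
    a = d_orig[iu]
    if np.any(a <= 0):
        raise ValueError("distortion rate undefined: zero off-diagonal original distance")
    return float(np.mean(np.abs(d_embedded[iu] - a) / a))


def quality_report(d_high: np.ndarray, d_low: np.ndarray) -> QualityReport:
    """Full quality summary of one embedding against original distances."""
    Q = coranking_matrix(d_high, d_low)
    q_local, q_global = q_curve_and_split(Q)
    return QualityReport(
        q_local=q_local,
        q_global=q_global,
        shepard_r=shepard_correlation(d_high, d_low),
        distortion=distortion_rate(d_high, d_low),
    )
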