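"""Dimensionality baseline correction for comparing recurrence analyses
across phase spaces of different dimension.

For independent unit-variance coordinates the expected squared distance
between two random phase-space points is exactly 2 per dimension,

    L_D^2 = 2 D,

so the root-mean-square distance grows as sqrt(2D) and distances at
different dimensionalities are related by

    L_D = sqrt(L_{D+n}^2 - 2 n).

The law is implemented on RMS distances (for which it is exact); the
plain mean distance differs from the RMS by a D-dependent factor that is
below ~3% for D >= 3 and largest (about 18% for uniform variates) at
D = 1.  The same scaling appears whether extra dimensions are separately
measured variables or time-delayed surrogates of one variable.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "expected_distance",
    "project_distance",
    "add_dimensions",
    "rescale_threshold",
    "mean_squared_distance",
    "rms_distance",
    "threshold_for_rr",
]


def expected_distance(D: int) -> float:
    """RMS inter-point distance sqrt(2D) for D independent unit-variance dims."""
    if D < 1:
        raise ValueError("D must be >= 1")
    return float(np.sqrt(2.0 * D))


def project_distance(L_high: float, n: int) -> float:
    """Remove ``n`` independent unit-variance dimensions from a distance.

    Returns ``sqrt(L_high**2 - 2n)``; raises when ``L_high**2 <= 2n``
    (removing that many dimensions from so small a distance is
    unphysical).  ``n = 0`` is the identity.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    if n and L_high * L_high <= 2.0 * n:
        raise ValueError(f"L_high^2 = {L_high**2:.4g} must exceed 2n = {2 * n}")
    return float(np.sqrt(L_high * L_high - 2.0 * n))


def add_dimensions(L: float, n: int) -> float:
    """Inverse of :func:`project_distance`: ``sqrt(L**2 + 2n)``."""
    if n < 0:
        raise ValueError("n must be >= 0")
    return float(np.sqrt(L * L + 2.0 * n))


def rescale_threshold(T: float, D_from: int, D_to: int) -> float:
    """Rescale a recurrence threshold between phase-space dimensionalities.

    Under the ``L^2 = 2D`` law distances grow as sqrt(D), so scaling the
    threshold by ``sqrt(D_to / D_from)`` approximately preserves the
    recurrence rate of independent, unit-variance data across dimension
    changes.
    """
    if D_from < 1 or D_to < 1:
        raise ValueError("dimensions must be >= 1")
    return float(T) * float(np.sqrt(D_to / D_from))


def mean_squared_distance(points: np.ndarray, chunk: int = 1024) -> float:
    """Mean squared Euclidean distance over all off-diagonal ordered pairs.

    Computed in row chunks so that n ~ 1e4 points stay within a modest
    memory budget.
    """
    X = np.asarray(points, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n = X.shape[0]
    if n < 2:
        raise ValueError("need at least two points")
    sq = np.einsum("ij,ij->i", X, X)
    total = 0.0
    for start in range(0, n, chunk):
        block = X[start : start + chunk]
        d2 = sq[start : start + chunk, None] + sq[None, :] - 2.0 * block @ X.T
        np.clip(d2, 0.0, None, out=d2)
        total += float(d2.sum())
    # the diagonal contributes exactly zero; divide by ordered off-diag pairs
    return total / (n * (n - 1))


def rms_distance(points: np.ndarray, chunk: int = 1024) -> float:
    """Root-mean-square inter-point distance (off-diagonal pairs)."""
    return float(np.sqrt(mean_squared_distance(points, chunk=chunk)))


def threshold_for_rr(distmat: np.ndarray, target_rr: float, theiler: int = 1) -> float:
    """Absolute threshold at which a plot attains a target recurrence rate.

    Takes the empirical ``target_rr`` quantile of the distances outside
    the Theiler window, so the achieved RR matches the target up to ties
    in the distance distribution (well within +-0.01 for continuous
    data).  This is the "keep percent recurrence constant" route for
    comparing analyses across dimensionalities.
    """
    if not 0.0 < target_rr < 1.0:
        raise ValueError("target_rr must be in (0, 1)")
    d = np.asarray(distmat)
    if d.shape[0] == d.shape[1] and theiler:
        offs = np.abs(np.arange(d.shape[0])[:, None] - np.arange(d.shape[1])[None, :])
        vals = d[offs >= theiler]
    else:
        vals = d.ravel()
    if vals.size == 0:
        raise ValueError("no distances outside the Theiler window")
    return float(np.quantile(vals, target_rr))
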