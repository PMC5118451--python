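"""Distance matrices and the four recurrence-plot constructions.

A recurrence plot marks the pairs of time indices whose phase-space states
lie within a threshold distance T of each other:

    RP_ij = Theta(T - ||V_i - V_j||),

with Theta the Heaviside step (Theta(0) = 1, so a distance exactly equal
to T counts as recurrent).  Variants differ only in where the two state
sequences come from: the same trajectory (auto), two separately embedded
trajectories (cross), the elementwise conjunction of several individual
plots (joint), or a single phase space whose coordinates are multiple
measured channels (multidimensional).

Thresholds may be given as absolute distances (``mode="absolute"``) or as
a fraction of the mean off-diagonal distance of the plot's own distance
matrix (``mode="meanfrac"``), which makes plots of phase spaces with
different scales or dimensionalities comparable.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .datatypes import EmbeddingSpec, PhaseSpace, RecurrenceMatrix, TimeSeriesSet
from .embedding import embed

__all__ = [
    "distance_matrix",
    "resolve_threshold",
    "recurrence_plot",
    "cross_recurrence_plot",
    "joint_recurrence_plot",
    "mdrp",
]

THRESHOLD_MODES = ("absolute", "meanfrac")


def distance_matrix(A: PhaseSpace, B: PhaseSpace | None = None) -> np.ndarray:
    """Euclidean distance between every pair of rows of A (and B).

    With ``B=None`` (or ``B is A``) returns the symmetric self-distance
    matrix with an exactly zero diagonal.
    """
    if B is None or B is A:
        d = cdist(A.points, A.points)
        np.fill_diagonal(d, 0.0)
        return d
    if A.dim != B.dim:
        raise ValueError(f"dimension mismatch: {A.dim} vs {B.dim}")
    return cdist(A.points, B.points)


def resolve_threshold(distmat: np.ndarray, T: float, mode: str = "meanfrac") -> float:
    """Turn a threshold specification into an absolute distance.

    ``absolute`` returns ``T`` unchanged; ``meanfrac`` returns ``T`` times
    the mean off-diagonal distance (mean over all cells for rectangular
    matrices).  A degenerate all-zero distance matrix has no scale to be
    relative to and raises.
    """
    if T <= 0:
        raise ValueError("threshold must be positive")
    if mode == "absolute":
        return float(T)
    if mode != "meanfrac":
        raise ValueError(f"unknown threshold mode {mode!r}")
    d = np.asarray(distmat)
    if d.shape[0] == d.shape[1]:
        mask = ~np.eye(d.shape[0], dtype=bool)
        mean = d[mask].mean() if mask.any() else 0.0
    else:
        mean = d.mean()
    if mean == 0.0:
        raise ValueError("degenerate distance matrix: all distances are zero")
    return float(T) * float(mean)


def _threshold(d: np.ndarray, T: float, mode: str) -> tuple[np.ndarray, float]:
    T_abs = resolve_threshold(d, T, mode)
    return d <= T_abs, T_abs


def recurrence_plot(
    P: PhaseSpace,
    T: float,
    mode: str = "meanfrac",
    theiler: int = 1,
    kind: str = "auto",
) -> RecurrenceMatrix:
    """Auto-recurrence plot of a single phase space.

    All cells are stored (including the line of identity); the Theiler
    window ``theiler`` is carried as metadata and applied when measures
    are computed (``theiler=1`` excludes only the line of identity).
    """
    M, T_abs = _threshold(distance_matrix(P), T, mode)
    return RecurrenceMatrix(
        M, kind=kind, threshold=T_abs, threshold_input=T, threshold_mode=mode,
        theiler=theiler,
    )


def cross_recurrence_plot(
    Px: PhaseSpace, Py: PhaseSpace, T: float, mode: str = "meanfrac"
) -> RecurrenceMatrix:
    """Cross-recurrence plot between two separately embedded trajectories.

    Generally non-square; there is no line of identity and no Theiler
    masking.  Swapping the arguments transposes the plot.
    """
    M, T_abs = _threshold(distance_matrix(Px, Py), T, mode)
    return RecurrenceMatrix(
        M, kind="cross", threshold=T_abs, threshold_input=T, threshold_mode=mode,
        theiler=0,
    )


def joint_recurrence_plot(
    spaces: Sequence[PhaseSpace],
    T: float | Sequence[float],
    mode: str = "meanfrac",
    theiler: int = 1,
) -> RecurrenceMatrix:
    """Joint recurrence plot: elementwise product of the individual plots.

    Each phase space gets its own auto-recurrence plot (per-space
    thresholds allowed by passing a sequence ``T``); only cells recurrent
    in every constituent plot survive.  For binary matrices the product
    equals the elementwise minimum.
    """
    if len(spaces) < 2:
        raise ValueError("need at least two phase spaces")
    n_rows = {s.n_rows for s in spaces}
    if len(n_rows) != 1:
        raise ValueError(f"phase spaces must share a row count, got {sorted(n_rows)}")
    thresholds = list(T) if np.iterable(T) else [float(T)] * len(spaces)
    if len(thresholds) != len(spaces):
        raise ValueError("one threshold per phase space required")
    M = None
    T_abs = []
    for s, t in zip(spaces, thresholds):
        Mi, ti = _threshold(distance_matrix(s), t, mode)
        T_abs.append(ti)
        M = Mi if M is None else (M & Mi)
    return RecurrenceMatrix(
        M, kind="joint", threshold=max(T_abs), threshold_input=np.max(thresholds),
        threshold_mode=mode, theiler=theiler, thresholds=tuple(T_abs),
    )


def mdrp(
    ts: TimeSeriesSet,
    spec: EmbeddingSpec,
    T: float,
    mode: str = "meanfrac",
    theiler: int = 1,
) -> RecurrenceMatrix:
    """Multidimensional recurrence plot of a multivariate series.

    Embeds the channels per ``spec`` (z-score, then ``m`` copies per
    channel at delay ``tau``) and thresholds the resulting self-distance
    matrix.  With a single channel this is exactly the classical
    recurrence plot of its delay embedding.
    """
    return recurrence_plot(embed(ts, spec), T, mode=mode, theiler=theiler, kind="multidim")
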