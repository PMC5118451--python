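"""Quantification of a recurrence plot via its diagonal line structure.

The four classical measures:

    RR  = recurrent cells / counted cells
    DET = recurrent cells on diagonal lines (length >= min) / recurrent cells
    ADL = mean diagonal line length
    LDL = longest diagonal line length

Diagonal lines are maximal runs of consecutive recurrent cells along
matrix diagonals; they mark stretches of time where two trajectory
segments evolve in parallel.  Cells inside the Theiler window
(``|i - j| < theiler``, the trivially recurrent neighbourhood of the line
of identity) are excluded from both the cell counts and the line scan.
Runs touching the matrix border count as lines (no edge correction).
"""

from __future__ import annotations

import numpy as np

from .datatypes import RecurrenceMatrix, RQAResult

__all__ = ["diagonal_lines", "rqa_measures"]


def _run_lengths(diag: np.ndarray) -> np.ndarray:
    """Lengths of maximal runs of True in a 1-D boolean array."""
    if not diag.any():
        return np.empty(0, dtype=int)
    padded = np.concatenate(([False], diag, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    return edges[1::2] - edges[::2]


def diagonal_lines(R: RecurrenceMatrix, min_len: int = 2) -> dict[int, int]:
    """Histogram (length -> count) of diagonal lines of length >= ``min_len``.

    Scans every diagonal offset outside the Theiler window of ``R``
    (``|offset| >= R.theiler``; all offsets when the window is 0).  Each
    maximal run of recurrent cells is counted once per (offset, start).
    """
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    M = R.M
    n_i, n_j = M.shape
    hist: dict[int, int] = {}
    for k in range(-(n_i - 1), n_j):
        if R.theiler and abs(k) < R.theiler:
            continue
        for length in _run_lengths(np.diagonal(M, k)):
            if length >= min_len:
                hist[int(length)] = hist.get(int(length), 0) + 1
    return hist


def rqa_measures(R: RecurrenceMatrix, min_len: int = 2) -> RQAResult:
    """Compute RR, DET, ADL and LDL for a recurrence plot.

    RR excludes Theiler-masked cells from both numerator and denominator,
    keeping it comparable across Theiler settings.  When the plot has no
    recurrences or no lines of length >= ``min_len``, DET/ADL/LDL are
    reported as 0 with ``no_lines`` set.
    """
    mask = R.theiler_mask()
    n_cells = int(mask.sum())
    n_recurrent = int((R.M & mask).sum())
    rr = n_recurrent / n_cells if n_cells else 0.0

    hist = diagonal_lines(R, min_len=min_len)
    n_lines = sum(hist.values())
    points_on_lines = sum(length * count for length, count in hist.items())
    if n_recurrent and n_lines:
        det = points_on_lines / n_recurrent
        adl = points_on_lines / n_lines
        ldl = max(hist)
        no_lines = False
    else:
        det, adl, ldl, no_lines = 0.0, 0.0, 0, True
    return RQAResult(
        rr=rr,
        det=det,
        adl=adl,
        ldl=int(ldl),
        line_hist=hist,
        n_recurrent=n_recurrent,
        n_cells=n_cells,
        min_line_length=min_len,
        no_lines=no_lines,
    )
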