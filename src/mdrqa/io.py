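"""Delimited-text input/output for time series, recurrence plots and measures.

Time series travel as headered CSV/TSV, one column per channel, one row
per sample, with an optional leading time column (named ``t`` or ``time``)
that must be a uniform grid.  Recurrence plots are exported as a sparse
coordinate CSV of the recurrent cells (1-based ``i,j`` indices, upper
triangle only for symmetric kinds) next to a JSON metadata sidecar that
makes the export round-trip losslessly.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import RecurrenceMatrix, RQAResult, TimeSeriesSet

__all__ = [
    "read_timeseries",
    "write_timeseries",
    "write_rp",
    "read_rp",
    "measures_row",
    "write_measures",
]

_TIME_NAMES = {"t", "time"}
_GRID_RTOL = 1e-6  # max relative deviation of a time column from a uniform grid


def read_timeseries(path: str | Path) -> TimeSeriesSet:
    """Read a headered CSV/TSV into a :class:`TimeSeriesSet`.

    A leading column named ``t`` or ``time`` (case-insensitive) is taken
    as the sample grid: it must be uniform to within ``1e-6`` of its step
    and sets ``dt``/``t0``; all other columns become channels and must be
    numeric.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.read_csv(path, sep=sep)
    if df.shape[0] < 1 or df.shape[1] < 1:
        raise ValueError(f"{path}: empty table")
    for col in df.columns:
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise ValueError(f"{path}: non-numeric cell at row {row + 2}, column {col!r}")
        if df[col].isna().any():
            row = int(np.flatnonzero(df[col].isna())[0])
            raise ValueError(f"{path}: missing value at row {row + 2}, column {col!r}")

    dt, t0 = 1.0, 0.0
    first = str(df.columns[0])
    if first.strip().lower() in _TIME_NAMES:
        t = df.iloc[:, 0].to_numpy(dtype=float)
        df = df.iloc[:, 1:]
        if df.shape[1] == 0:
            raise ValueError(f"{path}: only a time column, no channels")
        if t.size > 1:
            steps = np.diff(t)
            dt = float(np.mean(steps))
            if dt <= 0 or np.abs(steps - dt).max() > _GRID_RTOL * abs(dt):
                raise ValueError(f"{path}: time column is not a uniform grid")
        t0 = float(t[0])
    return TimeSeriesSet(df.to_numpy(dtype=float), tuple(str(c) for c in df.columns), dt=dt, t0=t0)


def write_timeseries(ts: TimeSeriesSet, path: str | Path, time_column: bool = True) -> None:
    """Write a :class:`TimeSeriesSet` as CSV (optionally with a time column)."""
    path = Path(path)
    df = pd.DataFrame(ts.data, columns=list(ts.channels))
    if time_column:
        df.insert(0, "time", ts.times)
    df.to_csv(path, index=False, float_format="%.17g")


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_rp(R: RecurrenceMatrix, path: str | Path) -> None:
    """Export a recurrence plot as sparse 1-based ``i,j`` coordinates + sidecar.

    Symmetric kinds (auto/multidim/joint) store only the upper triangle
    (``i <= j``) with ``symmetric: true`` in the sidecar; cross plots
    store every recurrent cell.  An empty plot writes a header-only file.
    """
    path = Path(path)
    symmetric = R.kind != "cross"
    ii, jj = np.nonzero(R.M)
    if symmetric:
        keep = ii <= jj
        ii, jj = ii[keep], jj[keep]
    pd.DataFrame({"i": ii + 1, "j": jj + 1}).to_csv(path, index=False)
    meta = {
        "kind": R.kind,
        "threshold": R.threshold,
        "threshold_input": None if np.isnan(R.threshold_input) else R.threshold_input,
        "threshold_mode": R.threshold_mode,
        "norm": R.norm,
        "theiler": R.theiler,
        "shape": list(R.shape),
        "symmetric": symmetric,
        "indexing": "1-based",
    }
    _sidecar(path).write_text(json.dumps(meta, indent=2) + "\n")


def read_rp(path: str | Path) -> RecurrenceMatrix:
    """Reconstruct a recurrence plot written by :func:`write_rp`."""
    path = Path(path)
    meta = json.loads(_sidecar(path).read_text())
    coords = pd.read_csv(path)
    M = np.zeros(tuple(meta["shape"]), dtype=bool)
    if len(coords):
        ii = coords["i"].to_numpy() - 1
        jj = coords["j"].to_numpy() - 1
        M[ii, jj] = True
        if meta["symmetric"]:
            M[jj, ii] = True
    t_in = meta.get("threshold_input")
    return RecurrenceMatrix(
        M,
        kind=meta["kind"],
        threshold=meta["threshold"],
        threshold_input=float("nan") if t_in is None else t_in,
        threshold_mode=meta["threshold_mode"],
        theiler=meta["theiler"],
        norm=meta.get("norm", "euclidean"),
    )


def measures_row(
    result: RQAResult, R: RecurrenceMatrix, n: int, m: int, tau: int
) -> dict:
    """Flat record of one analysis, suitable for a CSV/JSON report."""
    return {
        "kind": R.kind,
        "n": n,
        "m": m,
        "tau": tau,
        "threshold": R.threshold,
        "threshold_mode": R.threshold_mode,
        "theiler": R.theiler,
        "minlen": result.min_line_length,
        "RR": result.rr,
        "DET": result.det,
        "ADL": result.adl,
        "LDL": result.ldl,
    }


def write_measures(rows: list[dict], path: str | Path) -> None:
    pd.DataFrame(rows).to_csv(Path(path), index=False)
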