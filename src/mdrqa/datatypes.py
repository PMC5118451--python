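"""Core containers shared by every analysis stage.

All containers are thin dataclasses around NumPy arrays: a
:class:`TimeSeriesSet` holds uniformly sampled channels, a
:class:`PhaseSpace` holds the time-ordered phase-space vectors built from
them, a :class:`RecurrenceMatrix` holds a thresholded distance matrix, and
an :class:`RQAResult` holds the diagonal-line statistics quantifying it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class TimeSeriesSet:
    """Uniformly sampled multivariate time series.

    Parameters
    ----------
    data : ndarray, shape (n_samples, n_channels)
        One column per channel, one row per sample.
    channels : tuple of str
        Channel names, in column order.
    dt : float
        Sampling interval. Sample ``k`` is at time ``t0 + k * dt``.
    t0 : float
        Time of the first sample.
    """

    data: np.ndarray
    channels: tuple[str, ...]
    dt: float = 1.0
    t0: float = 0.0

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        if data.ndim == 1:
            data = data[:, None]
        if data.ndim != 2:
            raise ValueError("data must be a (n_samples, n_channels) array")
        object.__setattr__(self, "data", data)
        if len(self.channels) != data.shape[1]:
            raise ValueError(
                f"{len(self.channels)} channel names for {data.shape[1]} columns"
            )
        if self.dt <= 0:
            raise ValueError("dt must be positive")

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def times(self) -> np.ndarray:
        """Arithmetic sample grid ``t0 + k * dt``."""
        return self.t0 + np.arange(self.n_samples) * self.dt

    def channel(self, name: str) -> np.ndarray:
        """Return a single channel by name as a 1-D array."""
        try:
            idx = self.channels.index(name)
        except ValueError:
            raise KeyError(f"no channel named {name!r}") from None
        return self.data[:, idx]

    def select(self, names: tuple[str, ...] | list[str]) -> "TimeSeriesSet":
        """Subset of channels, preserving order of `names`."""
        cols = [self.channels.index(n) for n in names]
        return TimeSeriesSet(self.data[:, cols], tuple(names), self.dt, self.t0)


@dataclass(frozen=True)
class EmbeddingSpec:
    """How to turn channels into phase-space coordinates.

    ``m`` is the number of copies taken per channel (the original plus
    ``m - 1`` delayed copies), ``tau`` the delay in samples.  The total
    phase-space dimension is ``N * m`` for ``N`` channels; ``m = 1`` uses
    the channels as-is with no delayed copies.
    """

    m: int = 1
    tau: int = 1
    zscore: bool = True

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("m must be >= 1")
        if self.tau < 1:
            raise ValueError("tau must be >= 1")

    def total_dim(self, n_channels: int) -> int:
        return n_channels * self.m


@dataclass(frozen=True)
class PhaseSpace:
    """Matrix of time-ordered phase-space vectors.

    ``points[i]`` is the state visited at (embedded) time index ``i``;
    columns are phase-space dimensions.  ``source`` records which channels
    and which embedding produced each column.
    """

    points: np.ndarray
    source: str = ""

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim == 1:
            pts = pts[:, None]
        if pts.ndim != 2:
            raise ValueError("points must be 2-D")
        if not np.isfinite(pts).all():
            raise ValueError("phase-space points must be finite")
        object.__setattr__(self, "points", pts)

    @property
    def n_rows(self) -> int:
        return self.points.shape[0]

    @property
    def dim(self) -> int:
        return self.points.shape[1]


@dataclass(frozen=True)
class RecurrenceMatrix:
    """Binary recurrence matrix plus the settings that produced it.

    ``kind`` is one of ``auto``, ``cross``, ``joint``, ``multidim``.
    ``threshold`` is the resolved absolute distance threshold actually
    applied; ``threshold_input`` and ``threshold_mode`` record how it was
    specified (``absolute`` or ``meanfrac`` = fraction of the mean
    off-diagonal distance).  ``theiler`` is the Theiler window ``w``: cells
    with ``|i - j| < w`` are excluded when measures are computed (``w = 1``
    masks only the line of identity, ``w = 0`` masks nothing).
    """

    M: np.ndarray
    kind: str
    threshold: float
    threshold_input: float = float("nan")
    threshold_mode: str = "absolute"
    theiler: int = 0
    norm: str = "euclidean"
    thresholds: tuple[float, ...] = field(default=())

    _KINDS = ("auto", "cross", "joint", "multidim")

    def __post_init__(self) -> None:
        M = np.asarray(self.M)
        if M.dtype != bool:
            M = M.astype(bool)
        object.__setattr__(self, "M", M)
        if self.kind not in self._KINDS:
            raise ValueError(f"kind must be one of {self._KINDS}")
        if self.kind != "cross" and M.shape[0] != M.shape[1]:
            raise ValueError(f"{self.kind} plot must be square")
        if self.theiler < 0:
            raise ValueError("theiler must be >= 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.M.shape

    @property
    def is_square(self) -> bool:
        return self.M.shape[0] == self.M.shape[1]

    def theiler_mask(self) -> np.ndarray:
        """Boolean mask of cells that count for measures (True = counted)."""
        n_i, n_j = self.M.shape
        if self.theiler == 0:
            return np.ones((n_i, n_j), dtype=bool)
        offs = np.arange(n_i)[:, None] - np.arange(n_j)[None, :]
        return np.abs(offs) >= self.theiler


@dataclass(frozen=True)
class RQAResult:
    """The four classical recurrence measures and their raw ingredients.

    ``rr`` and ``det`` are fractions in [0, 1]; ``rr_pct`` / ``det_pct``
    expose them in percent.  ``adl``/``ldl`` are in points (matrix cells
    along a diagonal).  ``line_hist`` maps diagonal line length to count
    (lengths >= the minimum line length only).  ``no_lines`` flags plots
    where DET/ADL/LDL are undefined and reported as 0.
    """

    rr: float
    det: float
    adl: float
    ldl: int
    line_hist: dict[int, int]
    n_recurrent: int
    n_cells: int
    min_line_length: int
    no_lines: bool = False

    @property
    def rr_pct(self) -> float:
        return 100.0 * self.rr

    @property
    def det_pct(self) -> float:
        return 100.0 * self.det

    def as_dict(self) -> dict:
        return {
            "RR": self.rr,
            "DET": self.det,
            "ADL": self.adl,
            "LDL": self.ldl,
            "n_recurrent": self.n_recurrent,
            "n_cells": self.n_cells,
        }
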