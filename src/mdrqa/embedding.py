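"""Phase-space construction: z-scoring, time-delay embedding, multivariate
stacking, and their combination.

For a single observable ``x`` of length ``n``, the classical Takens
reconstruction with dimension ``D`` and delay ``tau`` forms the
``n - (D-1)*tau`` row vectors

    V_i = (x_i, x_{i+tau}, ..., x_{i+(D-1)tau}).

For ``N`` simultaneously measured observables the multidimensional variant
uses the measured channels themselves as phase-space coordinates,

    W_i = (y_{1,i}, ..., y_{N,i}),

optionally with each channel additionally delay-embedded ``m`` times, for a
total dimension ``D = N*m``.  "Embedded once" in the multivariate setting
means one delayed copy in addition to the original, i.e. ``m = 2``.
"""

from __future__ import annotations

import numpy as np

from .datatypes import EmbeddingSpec, PhaseSpace, TimeSeriesSet

__all__ = [
    "zscore_channels",
    "delay_embed",
    "stack_multivariate",
    "embed_multivariate",
    "embed",
]


def zscore_channels(ts: TimeSeriesSet, ddof: int = 1) -> TimeSeriesSet:
    """Normalize every channel to mean 0 and standard deviation 1.

    Uses the sample standard deviation (``ddof=1``) by convention.  A
    constant channel cannot be normalized and raises ``ValueError`` naming
    the offending channel.
    """
    sd = ts.data.std(axis=0, ddof=ddof)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        names = ", ".join(ts.channels[i] for i in bad)
        raise ValueError(f"cannot z-score constant channel(s): {names}")
    data = (ts.data - ts.data.mean(axis=0)) / sd
    return TimeSeriesSet(data, ts.channels, ts.dt, ts.t0)


def _check_length(n: int, m: int, tau: int) -> int:
    n_rows = n - (m - 1) * tau
    if n_rows < 1:
        raise ValueError(
            f"series of length {n} too short for m={m}, tau={tau}: "
            f"need at least {(m - 1) * tau + 1} samples"
        )
    return n_rows


def delay_embed(channel: np.ndarray, D: int, tau: int, name: str = "x") -> PhaseSpace:
    """Time-delay embed a single channel into ``D`` dimensions with delay ``tau``.

    Row ``i`` (0-based) is ``(x_i, x_{i+tau}, ..., x_{i+(D-1)tau})``; there
    are ``n - (D-1)*tau`` rows.  Column ``j`` is the input shifted by
    ``j*tau`` samples.  ``D = 1`` returns the channel unchanged as a single
    column.
    """
    x = np.asarray(channel, dtype=float).ravel()
    if D < 1 or tau < 1:
        raise ValueError("D and tau must be >= 1")
    n_rows = _check_length(x.size, D, tau)
    cols = [x[j * tau : j * tau + n_rows] for j in range(D)]
    return PhaseSpace(np.column_stack(cols), source=f"{name}[D={D},tau={tau}]")


def stack_multivariate(ts: TimeSeriesSet) -> PhaseSpace:
    """Use the ``N`` measured channels directly as phase-space coordinates.

    Row ``i`` is ``(y_1(t_i), ..., y_N(t_i))``: no delayed copies, all
    ``n`` samples kept.
    """
    return PhaseSpace(ts.data.copy(), source="+".join(ts.channels) + "[m=1]")


def embed_multivariate(ts: TimeSeriesSet, m: int, tau: int) -> PhaseSpace:
    """Stack ``N`` channels, each delay-embedded with ``m`` copies at delay ``tau``.

    Column order is channel-major: all ``m`` delayed copies of channel 1,
    then channel 2, and so on.  Total dimension ``N*m``; row count
    ``n - (m-1)*tau``.  Reduces bit-exactly to :func:`stack_multivariate`
    for ``m=1`` and to :func:`delay_embed` for ``N=1``.
    """
    if m < 1 or tau < 1:
        raise ValueError("m and tau must be >= 1")
    n_rows = _check_length(ts.n_samples, m, tau)
    cols = []
    for j in range(ts.n_channels):
        x = ts.data[:, j]
        cols.extend(x[k * tau : k * tau + n_rows] for k in range(m))
    src = "+".join(ts.channels) + f"[m={m},tau={tau}]"
    return PhaseSpace(np.column_stack(cols), source=src)


def embed(ts: TimeSeriesSet, spec: EmbeddingSpec) -> PhaseSpace:
    """Apply an :class:`EmbeddingSpec`: optional z-scoring, then embedding."""
    if spec.zscore:
        ts = zscore_channels(ts)
    return embed_multivariate(ts, spec.m, spec.tau)
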