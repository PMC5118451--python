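"""Shared fixtures: the canonical Lorenz analysis set and brute-force oracles.

The Lorenz benchmark (sigma=10, rho=28, beta=8/3, t in [0, 20], dt=0.0162,
z-scored) with per-channel delay embeddings (D=3, tau=4, absolute
threshold 0.1) and the three-channel multidimensional plot (m=1, threshold
0.08 as a fraction of mean distance) is expensive enough to share
session-wide; several test modules and the acceptance suite compare
against it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pytest

import mdrqa as M

# reference analysis settings for the Lorenz benchmark
LORENZ_RQA = dict(D=3, tau=4, T=0.1, mode="absolute")
LORENZ_MDRQA = dict(T=0.08, mode="meanfrac")
THEILER = 1
MIN_LEN = 2


@dataclass(frozen=True)
class LorenzAnalysis:
    ts: M.TimeSeriesSet                     # z-scored channels
    spaces: dict[str, M.PhaseSpace]         # per-channel delay embeddings
    rps: dict[str, M.RecurrenceMatrix]      # per-channel recurrence plots
    md: M.RecurrenceMatrix                  # multidimensional plot
    joint: M.RecurrenceMatrix               # joint plot of the three RPs
    measures: dict[str, M.RQAResult]        # keys x, y, z, md, joint


def lorenz_reference_analysis() -> LorenzAnalysis:
    """Run the full benchmark analysis once (also used by scripts/acceptance.py)."""
    ts = M.simulate_lorenz(M.LorenzParams(), zscore=True)
    spaces = {
        c: M.delay_embed(ts.channel(c), LORENZ_RQA["D"], LORENZ_RQA["tau"], name=c)
        for c in ts.channels
    }
    rps = {
        c: M.recurrence_plot(
            spaces[c], LORENZ_RQA["T"], mode=LORENZ_RQA["mode"], theiler=THEILER
        )
        for c in ts.channels
    }
    md = M.mdrp(
        ts,
        M.EmbeddingSpec(m=1, tau=1, zscore=False),
        LORENZ_MDRQA["T"],
        mode=LORENZ_MDRQA["mode"],
        theiler=THEILER,
    )
    joint = M.joint_recurrence_plot(
        list(spaces.values()), LORENZ_RQA["T"], mode=LORENZ_RQA["mode"], theiler=THEILER
    )
    measures = {c: M.rqa_measures(rps[c], MIN_LEN) for c in ts.channels}
    measures["md"] = M.rqa_measures(md, MIN_LEN)
    measures["joint"] = M.rqa_measures(joint, MIN_LEN)
    return LorenzAnalysis(ts, spaces, rps, md, joint, measures)


@pytest.fixture(scope="session")
def lorenz() -> LorenzAnalysis:
    return lorenz_reference_analysis()


# ----------------------------------------------------------------- oracles
# Deliberately naive reimplementations used only to check the fast paths.

def brute_distance_matrix(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    out = np.empty((len(A), len(B)))
    for i in range(len(A)):
        for j in range(len(B)):
            out[i, j] = np.sqrt(np.sum((A[i] - B[j]) ** 2))
    return out


def brute_plot(A: np.ndarray, B: np.ndarray, T: float) -> np.ndarray:
    d = brute_distance_matrix(A, B)
    out = np.zeros(d.shape, dtype=bool)
    for i in range(d.shape[0]):
        for j in range(d.shape[1]):
            out[i, j] = d[i, j] <= T  # Heaviside(0) = 1: equality recurs
    return out


def brute_diagonal_histogram(Mat: np.ndarray, theiler: int, min_len: int) -> dict[int, int]:
    """Walk every diagonal cell by cell, counting maximal runs."""
    n_i, n_j = Mat.shape
    hist: dict[int, int] = {}
    for k in range(-(n_i - 1), n_j):
        if theiler and abs(k) < theiler:
            continue
        i, j = (max(0, -k), max(0, k))
        run = 0
        while i < n_i and j < n_j:
            if Mat[i, j]:
                run += 1
            else:
                if run >= min_len:
                    hist[run] = hist.get(run, 0) + 1
                run = 0
            i += 1
            j += 1
        if run >= min_len:
            hist[run] = hist.get(run, 0) + 1
    return hist
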