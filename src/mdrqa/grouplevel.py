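"""Systematic multi-level recurrence analysis of groups.

A group of N simultaneously recorded channels (one per member) can be
analysed at every level of aggregation: level k runs the multidimensional
recurrence analysis on each of the C(N, k) k-member subsets and averages
the four measures across subsets.  Level 1 is the average individual
analysis (classical RQA per channel), level 2 the average over all pairs,
level N the single whole-group analysis.

Per-team measures at a given level can then be regressed (ordinary least
squares, four predictors RR/DET/ADL/LDL plus intercept) on a per-team
outcome; the variance explained at each level localizes where in the
group hierarchy the outcome-relevant dynamics live.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .datatypes import EmbeddingSpec, RQAResult, TimeSeriesSet
from .measures import rqa_measures
from .recurrence import mdrp

__all__ = [
    "LevelResult",
    "RegressionReport",
    "mdrqa_level",
    "regress_outcome",
    "r2_threshold",
    "level_sweep",
]

MEASURE_NAMES = ("RR", "DET", "ADL", "LDL")


@dataclass(frozen=True)
class LevelResult:
    """Per-subset measures at one aggregation level plus their average."""

    level: int
    subsets: tuple[tuple[str, ...], ...]
    per_subset: tuple[RQAResult, ...]
    averaged: dict[str, float]

    def as_row(self) -> dict[str, float]:
        return {"level": self.level, **self.averaged}


@dataclass(frozen=True)
class RegressionReport:
    """OLS fit of an outcome on the four recurrence measures."""

    r2: float
    df_pred: int
    df_resid: int
    r2_threshold: float
    alpha: float
    condition_number: float
    collinear: bool

    @property
    def significant(self) -> bool:
        return self.r2 > self.r2_threshold


def mdrqa_level(
    ts: TimeSeriesSet,
    k: int,
    spec: EmbeddingSpec,
    T: float,
    mode: str = "meanfrac",
    theiler: int = 1,
    min_len: int = 2,
) -> LevelResult:
    """Level-k analysis: MdRQA on every k-channel subset, measures averaged.

    Averaging (arithmetic, including LDL) is over the C(N, k) subsets and
    is invariant to channel order.
    """
    if not 1 <= k <= ts.n_channels:
        raise ValueError(f"level k={k} outside 1..{ts.n_channels}")
    subsets = tuple(combinations(ts.channels, k))
    results = []
    for subset in subsets:
        sub_ts = ts.select(list(subset))
        R = mdrp(sub_ts, spec, T, mode=mode, theiler=theiler)
        results.append(rqa_measures(R, min_len=min_len))
    averaged = {
        "RR": float(np.mean([r.rr for r in results])),
        "DET": float(np.mean([r.det for r in results])),
        "ADL": float(np.mean([r.adl for r in results])),
        "LDL": float(np.mean([r.ldl for r in results])),
    }
    return LevelResult(level=k, subsets=subsets, per_subset=tuple(results), averaged=averaged)


def r2_threshold(df_pred: int, df_resid: int, alpha: float = 0.05) -> float:
    """Minimum R^2 significant at level ``alpha`` for an OLS F test.

    Inverts the F statistic ``F = (R^2 / p) / ((1 - R^2) / df_resid)``
    at its critical value: ``R^2* = p F* / (p F* + df_resid)``.
    """
    if df_pred < 1 or df_resid < 1:
        raise ValueError("degrees of freedom must be >= 1")
    f_crit = stats.f.ppf(1.0 - alpha, df_pred, df_resid)
    return float(df_pred * f_crit / (df_pred * f_crit + df_resid))


def regress_outcome(
    X: np.ndarray | pd.DataFrame,
    y: np.ndarray,
    alpha: float = 0.05,
    cond_warn: float = 1e8,
) -> RegressionReport:
    """OLS of a per-team outcome on the four per-team measures.

    ``X`` is (teams x 4) in the order RR, DET, ADL, LDL; an intercept is
    added.  Collinear predictors do not fail the fit (statsmodels uses a
    pseudoinverse) but are flagged via the design condition number.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2-D (teams x measures)")
    if X.shape[0] != y.size:
        raise ValueError("X and y disagree on the number of teams")
    if X.shape[0] < X.shape[1] + 2:
        raise ValueError(f"need at least {X.shape[1] + 2} teams for a {X.shape[1]}-predictor fit")
    design = sm.add_constant(X, has_constant="add")
    fit = sm.OLS(y, design).fit()
    df_pred = X.shape[1]
    df_resid = int(fit.df_resid)
    # constant outcome: statsmodels reports centered R^2 of nan/0 edge cases
    r2 = float(fit.rsquared) if np.isfinite(fit.rsquared) else 0.0
    if np.allclose(y, y[0]):
        r2 = 0.0
    cond = float(np.linalg.cond(design))
    return RegressionReport(
        r2=r2,
        df_pred=df_pred,
        df_resid=df_resid,
        r2_threshold=r2_threshold(df_pred, df_resid, alpha),
        alpha=alpha,
        condition_number=cond,
        collinear=bool(cond > cond_warn),
    )


def level_sweep(
    teams: Sequence[TimeSeriesSet],
    outcomes: np.ndarray | pd.DataFrame,
    spec: EmbeddingSpec,
    T: float,
    mode: str = "meanfrac",
    theiler: int = 1,
    min_len: int = 2,
    levels: Sequence[int] | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """R^2 of every outcome on the averaged measures, per aggregation level.

    ``outcomes`` holds one row per team and one column per outcome
    (a bare vector is treated as a single outcome).  Returns a tidy frame
    with columns level, outcome, r2, r2_threshold, significant.
    """
    if not teams:
        raise ValueError("no teams given")
    n_channels = {t.n_channels for t in teams}
    if len(n_channels) != 1:
        raise ValueError("all teams must have the same number of channels")
    N = n_channels.pop()
    if levels is None:
        levels = range(1, N + 1)
    out = pd.DataFrame(outcomes)
    if out.shape[0] != len(teams):
        raise ValueError("one outcome row per team required")

    rows = []
    for k in levels:
        X = np.array(
            [
                [mdrqa_level(t, k, spec, T, mode, theiler, min_len).averaged[m] for m in MEASURE_NAMES]
                for t in teams
            ]
        )
        for col in out.columns:
            rep = regress_outcome(X, out[col].to_numpy(), alpha=alpha)
            rows.append(
                {
                    "level": k,
                    "outcome": col,
                    "r2": rep.r2,
                    "r2_threshold": rep.r2_threshold,
                    "significant": rep.significant,
                }
            )
    return pd.DataFrame(rows)
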