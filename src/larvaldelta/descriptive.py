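"""Descriptive parasitology: prevalence, mean intensity, length comparisons.

Prevalence is the percentage of host larvae in a sample carrying at least one
parasite; mean intensity is the mean number of parasites per *parasitized*
larva (unparasitized hosts excluded), so it is always >= 1.  Host-length
comparisons use a balanced seeded subsample of unparasitized larvae against
all parasitized ones; host-parasite length association uses Spearman rank
correlation with an exact permutation p-value at small n.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from math import isfinite
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .survey_data import Dataset


class UndefinedValueError(ValueError):
    """The requested quantity has no defined value on this input."""


class InsufficientDataError(ValueError):
    """Too few observations to run the requested test."""


def prevalence(n_parasitized: int, n_collected: int) -> float:
    """Percentage of parasitized larvae, 100 * n_parasitized / n_collected."""
    if n_collected == 0:
        raise UndefinedValueError("prevalence undefined when no larvae were collected")
    if not 0 <= n_parasitized <= n_collected:
        raise ValueError("require 0 <= n_parasitized <= n_collected")
    return 100.0 * n_parasitized / n_collected


def mean_intensity(n_parasites: int, n_parasitized: int) -> float:
    """Mean parasites per parasitized larva, n_parasites / n_parasitized."""
    if n_parasitized == 0:
        raise UndefinedValueError(
            "mean intensity undefined on samples with no parasitized larvae"
        )
    if n_parasites < n_parasitized:
        raise ValueError("each parasitized larva carries at least one parasite")
    return n_parasites / n_parasitized


@dataclass(frozen=True)
class TTestResult:
    t_stat: float
    df: float
    p_value: float
    n1: int
    n2: int
    seed: int


def length_ttest(
    parasitized_lengths: Sequence[float],
    unparasitized_lengths: Sequence[float],
    subsample_size: Optional[int] = None,
    seed: int = 0,
    welch: bool = False,
) -> TTestResult:
    """Two-sample t-test of parasitized vs a seeded unparasitized subsample.

    All parasitized lengths are used against a uniform random subsample
    (without replacement) of the unparasitized ones; ``subsample_size``
    defaults to a balanced design (as many unparasitized as parasitized,
    capped at the available number).  Pooled-variance Student form by
    default; ``welch=True`` drops the equal-variance assumption.
    """
    par = np.asarray(parasitized_lengths, dtype=float)
    unpar = np.asarray(unparasitized_lengths, dtype=float)
    if par.size == 0 or unpar.size == 0:
        raise InsufficientDataError("both length collections must be nonempty")
    if subsample_size is None:
        subsample_size = min(par.size, unpar.size)
    if subsample_size > unpar.size:
        raise InsufficientDataError(
            f"subsample_size {subsample_size} exceeds {unpar.size} unparasitized larvae"
        )
    rng = np.random.default_rng(seed)
    sub = rng.choice(unpar, size=subsample_size, replace=False)
    if par.size < 2 or sub.size < 2:
        raise InsufficientDataError("need at least 2 observations per group")
    res = stats.ttest_ind(par, sub, equal_var=not welch)
    t = float(res.statistic)
    if not isfinite(t):  # identical constant groups: zero pooled variance
        t = 0.0
        p = 1.0
    else:
        p = float(res.pvalue)
    df = float(res.df) if welch else float(par.size + sub.size - 2)
    return TTestResult(t_stat=t, df=df, p_value=p, n1=int(par.size), n2=int(sub.size), seed=seed)


@dataclass(frozen=True)
class CorrelationResult:
    r_s: float
    n: int
    p_value: float
    method: str  # "exact_permutation" or "t_approximation"


#: Largest n for which the permutation null is enumerated exhaustively.
EXACT_PERMUTATION_MAX_N = 9


def spearman_correlation(
    host_lengths: Sequence[float], parasite_lengths: Sequence[float]
) -> CorrelationResult:
    """Spearman rank correlation with average ranks for ties.

    Two-sided p-value by exhaustive permutation for n <= 9 (the printed
    per-area sample sizes go as low as 3, where the large-sample t
    approximation is unreliable), by ``t = r_s * sqrt((n-2)/(1-r_s^2))``
    otherwise.
    """
    x = np.asarray(host_lengths, dtype=float)
    y = np.asarray(parasite_lengths, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired collections must have equal length")
    n = x.size
    if n < 3:
        raise InsufficientDataError("need at least 3 pairs")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        raise UndefinedValueError("zero rank variance: correlation undefined")
    rxc = rx - rx.mean()
    ryc = ry - ry.mean()
    denom = np.sqrt((rxc ** 2).sum() * (ryc ** 2).sum())
    r = float((rxc * ryc).sum() / denom)
    if n <= EXACT_PERMUTATION_MAX_N:
        perms = np.array(list(itertools.permutations(range(n))))
        r_all = (ryc[perms] @ rxc) / denom
        p = float(np.mean(np.abs(r_all) >= abs(r) - 1e-12))
        method = "exact_permutation"
    else:
        if abs(r) >= 1.0:
            p = 0.0
        else:
            t = r * np.sqrt((n - 2) / (1.0 - r * r))
            p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
        method = "t_approximation"
    return CorrelationResult(r_s=r, n=int(n), p_value=p, method=method)


@dataclass
class DatasetSummary:
    """Per-cell and per-stratum descriptive summary of a survey Dataset."""

    cells: pd.DataFrame  # one row per record with n_collected >= 1
    strata: pd.DataFrame  # one row per (area, season)


def summarize_dataset(dataset: Dataset) -> DatasetSummary:
    """Per-cell prevalence/intensity plus per-(area, season) margins.

    Cells with no larvae collected carry no defined prevalence and are
    excluded from the per-cell table; stratum totals sum ``n_collected``
    over *all* records, and prevalence extremes are taken over summarized
    cells.
    """
    frame = dataset.to_frame()
    cells = frame[frame["n_collected"] >= 1].copy()
    cells["prevalence_pct"] = 100.0 * cells["n_parasitized"] / cells["n_collected"]
    cells["mean_intensity"] = np.where(
        cells["n_parasitized"] > 0,
        cells["n_parasites"] / cells["n_parasitized"].replace(0, 1),
        np.nan,
    )
    strata_rows = []
    for (area, season), grp in frame.groupby(["area", "season"], sort=True):
        sub = cells[(cells["area"] == area) & (cells["season"] == season)]
        strata_rows.append(
            {
                "area": area,
                "season": season,
                "total_collected": int(grp["n_collected"].sum()),
                "total_parasitized": int(grp["n_parasitized"].sum()),
                "n_cells": int(len(sub)),
                "min_prevalence_pct": float(sub["prevalence_pct"].min()) if len(sub) else np.nan,
                "max_prevalence_pct": float(sub["prevalence_pct"].max()) if len(sub) else np.nan,
            }
        )
    return DatasetSummary(cells=cells.reset_index(drop=True), strata=pd.DataFrame(strata_rows))
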