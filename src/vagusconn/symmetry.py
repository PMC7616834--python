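"""Bilateral asymmetry indices and rank-correlation symmetry testing.

For a cluster's synaptic budget split by origin x target hemisphere
(LL, RR, LR, RL), the asymmetry index is

    AI_ipsi   = (LL - RR) / (LL + RR) * 100 %
    AI_contra = (LR - RL) / (LR + RL) * 100 %

AI is 0 for a perfectly mirrored circuit, +100 when the right-origin side is
empty, and undefined (NaN, logged) when both counts are zero. Across
clusters, ipsilateral vs contralateral budget percentages are compared with
Spearman's rank correlation (mid-ranks for ties, large-sample p-value).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .circuit import HemisphereBudget

logger = logging.getLogger(__name__)


class InsufficientDataError(ValueError):
    pass


def asymmetry_index(first: float, second: float) -> float:
    """(first - second) / (first + second) * 100.

    Pass (LL, RR) for the ipsilateral index or (LR, RL) for the
    contralateral one. Antisymmetric under argument swap, bounded in
    [-100, 100]; NaN (logged) when both counts are zero.
    """
    if first < 0 or second < 0:
        raise ValueError("synapse counts must be non-negative")
    tot = first + second
    if tot == 0:
        logger.info("asymmetry_index: both counts zero -> undefined")
        return math.nan
    return (first - second) / tot * 100.0


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rank correlation on mid-ranks with the standard large-sample
    p-value. Pairs with a missing member are dropped; fewer than 3 complete
    pairs raise :class:`InsufficientDataError`."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    keep = ~(np.isnan(x) | np.isnan(y))
    dropped = int((~keep).sum())
    if dropped:
        logger.info("spearman_rho: dropped %d incomplete pairs", dropped)
    x, y = x[keep], y[keep]
    if len(x) < 3:
        raise InsufficientDataError(
            f"need >= 3 complete pairs for Spearman correlation, got {len(x)}")
    res = stats.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


@dataclass(frozen=True)
class AsymmetryRecord:
    cluster: str
    direction: str
    AI_ipsi: float  # NaN iff LL + RR == 0
    AI_contra: float  # NaN iff LR + RL == 0


def symmetry_report(budgets: Sequence[HemisphereBudget],
                    on: str = "percent") -> tuple[pd.DataFrame, dict]:
    """Asymmetry indices per (cluster, direction) plus a per-direction
    Spearman correlation of ipsi- vs contralateral budgets across clusters.

    ``on`` selects whether the correlation runs on budget percentages
    (default, each cluster's LL+RR resp. LR+RL share of its total) or on raw
    counts. Undefined AI values are excluded pairwise; the exclusion count is
    reported in the summary.
    """
    if not budgets:
        raise InsufficientDataError("no hemisphere budgets supplied")
    if on not in ("percent", "count"):
        raise ValueError(f"on must be 'percent' or 'count', got {on!r}")
    rows = []
    for b in budgets:
        rows.append({
            "cluster": b.cluster, "direction": b.direction,
            "LL": b.LL, "RR": b.RR, "LR": b.LR, "RL": b.RL,
            "AI_ipsi": asymmetry_index(b.LL, b.RR),
            "AI_contra": asymmetry_index(b.LR, b.RL),
        })
    table = pd.DataFrame(rows)
    summary: dict = {"correlation_on": on, "directions": {}}
    for direction, grp in table.groupby("direction"):
        if on == "percent":
            tot = grp[["LL", "RR", "LR", "RL"]].sum(axis=1)
            with np.errstate(invalid="ignore", divide="ignore"):
                ipsi = 100.0 * (grp["LL"] + grp["RR"]) / tot.where(tot > 0)
                contra = 100.0 * (grp["LR"] + grp["RL"]) / tot.where(tot > 0)
        else:
            ipsi = (grp["LL"] + grp["RR"]).astype(float)
            contra = (grp["LR"] + grp["RL"]).astype(float)
        complete = int((~(ipsi.isna() | contra.isna())).sum())
        entry: dict = {"n_clusters": int(len(grp)),
                       "n_complete_pairs": complete,
                       "n_excluded": int(len(grp)) - complete}
        try:
            rho, p = spearman_rho(ipsi.to_numpy(), contra.to_numpy())
            entry.update(rho=rho, p=p)
        except InsufficientDataError as exc:
            entry.update(rho=None, p=None, error=str(exc))
        summary["directions"][direction] = entry
    return table, summary
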