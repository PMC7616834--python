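"""Geodesic synapse-placement analysis.

For one neuron, every synaptic input and output is located by its geodesic
distance along the arbor from a designated origin node (e.g. the nerve
junction where the arbor enters the CNS — the anticipated locus of spike
initiation). Inputs are measured at the postsynaptic node of the connector,
outputs at the presynaptic node. Distances grouped by partner class are
compared with a classical one-way F statistic; when every group has zero
within-group variance but means differ, F is reported as the +inf sentinel
with p = 0 and a warning.
"""

from __future__ import annotations

import logging
import math
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .circuit import synapse_pairs
from .skeletons import Skeleton

logger = logging.getLogger(__name__)

PLACEMENT_COLUMNS = ["neuron", "connector", "polarity", "partner_group",
                     "geodesic_nm"]


class InsufficientDataError(ValueError):
    pass


def synapse_distances(s: Skeleton, connectors: pd.DataFrame,
                      origin: int | None = None,
                      partner_group: Mapping[str, str] | None = None,
                      ) -> pd.DataFrame:
    """One PlacementRecord per synaptic pair on skeleton ``s``.

    ``origin`` defaults to the skeleton's annotated origin node. Partners
    absent from ``partner_group`` fall into 'other'. Connector nodes that do
    not exist on the skeleton raise a validation error listing every
    offender.
    """
    if origin is None:
        origin = s.origin_node
    if origin is None:
        raise ValueError(f"neuron {s.neuron_id}: no origin node supplied or annotated")
    if origin not in s:
        raise ValueError(f"neuron {s.neuron_id}: origin node {origin} absent")
    pairs = synapse_pairs(connectors)
    outgoing = pairs[pairs["pre_neuron"] == s.neuron_id]
    incoming = pairs[pairs["post_neuron"] == s.neuron_id]
    offenders = []
    for df, col in ((outgoing, "pre_node"), (incoming, "post_node")):
        for cid, node in zip(df["connector_id"], df[col]):
            if int(node) not in s:
                offenders.append((cid, int(node)))
    if offenders:
        raise ValueError(
            f"neuron {s.neuron_id}: connector nodes absent from skeleton: "
            f"{offenders}")
    dist = s.distances_from(origin)
    records = []
    for df, col, polarity, partner_col in (
            (incoming, "post_node", "input", "pre_neuron"),
            (outgoing, "pre_node", "output", "post_neuron")):
        for row in df.itertuples(index=False):
            partner = getattr(row, partner_col)
            group = "other" if partner_group is None else \
                partner_group.get(partner, "other")
            records.append((s.neuron_id, row.connector_id, polarity, group,
                            dist[int(getattr(row, col))]))
    return pd.DataFrame(records, columns=PLACEMENT_COLUMNS)


def group_order_test(records: pd.DataFrame,
                     groups: list[str] | None = None) -> tuple[pd.DataFrame, float, float]:
    """Per-group placement summaries plus the one-way F statistic on
    geodesic distance by partner group.

    Returns (summary, F, p); the summary has one row per group (n, mean,
    median) ordered by ascending mean distance. Requires >= 2 groups with
    >= 2 records each.
    """
    if groups is not None:
        records = records[records["partner_group"].isin(groups)]
    by_group = {g: sub["geodesic_nm"].to_numpy(dtype=float)
                for g, sub in records.groupby("partner_group")}
    by_group = {g: v for g, v in by_group.items() if len(v) >= 2}
    if len(by_group) < 2:
        raise InsufficientDataError(
            "group_order_test needs >= 2 partner groups with >= 2 synapses each")
    summary = pd.DataFrame(
        [{"partner_group": g, "n": len(v), "mean_nm": float(v.mean()),
          "median_nm": float(np.median(v))} for g, v in by_group.items()]
    ).sort_values("mean_nm", ignore_index=True)
    f_stat, p = one_way_f(list(by_group.values()))
    return summary, f_stat, p


def one_way_f(samples: list[np.ndarray]) -> tuple[float, float]:
    """Classical one-way F from between/within sums of squares.

    Degenerate case: zero within-group variance with differing means gives
    F = +inf with p = 0 (sentinel, logged); identical constant groups give
    F = 0, p = 1.
    """
    k = len(samples)
    ns = np.array([len(s) for s in samples])
    n = int(ns.sum())
    means = np.array([float(np.mean(s)) for s in samples])
    grand = float(np.concatenate(samples).mean())
    ss_between = float((ns * (means - grand) ** 2).sum())
    ss_within = float(sum(((s - m) ** 2).sum() for s, m in zip(samples, means)))
    df_between, df_within = k - 1, n - k
    if df_within <= 0:
        raise InsufficientDataError("not enough observations for within-group df")
    if ss_within == 0.0:
        if ss_between == 0.0:
            return 0.0, 1.0
        logger.warning("one_way_f: zero within-group variance with differing "
                       "means; F reported as +inf, p as 0")
        return math.inf, 0.0
    f_stat = (ss_between / df_between) / (ss_within / df_within)
    p = float(stats.f.sf(f_stat, df_between, df_within))
    return f_stat, p
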