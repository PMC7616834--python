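"""Direct and indirect sensory pathway weights onto target neurons.

The influence of a sensory neuron s on a target t is scored per pathway:

* direct:      score = f[s, t]
* one-layer:   score = f[s, i1] * f[i1, t]
* two-layer:   score = f[s, i1] * f[i1, i2] * f[i2, t]

where f[a, b] is the synaptic *input fraction* of a onto b — b's inputs from
a divided by b's total input count (the fraction is always normalized by the
POST neuron of the hop). Pathways are simple (no neuron revisited) and
strictly layered: sensory -> first interneuron layer (-> second layer) ->
target; interneuron-to-interneuron hops occur only at ``max_layers=2``.
Every distinct path is a separate record; the *pathway weight* of a sensory
modality on a target sums all direct and indirect path scores of that
modality's sensory neurons.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

PATHWAY_COLUMNS = ["source", "target", "via", "score"]


def _nonzero_map(f: pd.DataFrame, rows: Iterable[str],
                 cols: Iterable[str]) -> dict[str, dict[str, float]]:
    """Sparse row -> {col: fraction} view of f restricted to rows x cols,
    keeping only defined, nonzero entries."""
    cols = [c for c in cols if c in f.columns]
    sub = f.loc[[r for r in rows if r in f.index], cols]
    out: dict[str, dict[str, float]] = {}
    for r, row in sub.iterrows():
        vals = row[row.notna() & (row > 0)]
        if len(vals):
            out[r] = vals.to_dict()
    return out


def direct_scores(f: pd.DataFrame, sensory: Sequence[str],
                  targets: Sequence[str]) -> pd.DataFrame:
    """One record per (sensory, target) pair with nonzero input fraction;
    score = f[s, t]. Targets with undefined fraction columns (zero total
    inputs) yield no records and are logged."""
    undefined = [t for t in targets if t in f.columns and f[t].isna().all()]
    if undefined:
        logger.warning("direct_scores: targets with undefined input fractions "
                       "(zero inputs): %s", undefined)
    hop = _nonzero_map(f, sensory, targets)
    records = [(s, t, "", v) for s, tv in hop.items() for t, v in tv.items()]
    return _as_table(records)


def indirect_scores(f: pd.DataFrame, sensory: Sequence[str],
                    interneurons: Sequence[str], targets: Sequence[str],
                    max_layers: int = 2) -> pd.DataFrame:
    """All simple layered paths s -> i1 [-> i2] -> t with every hop nonzero.

    ``max_layers`` 1 allows a single interneuron per path; 2 additionally
    allows one interneuron-to-interneuron hop. Paths revisiting a neuron are
    excluded. Hops into a neuron whose fraction column is undefined are
    skipped and logged.
    """
    if max_layers not in (1, 2):
        raise ValueError(f"max_layers must be 1 or 2, got {max_layers}")
    overlap = (set(sensory) & set(interneurons)) | (set(sensory) & set(targets)) \
        | (set(interneurons) & set(targets))
    if overlap:
        raise ValueError(f"sensory/interneuron/target sets overlap: {sorted(overlap)}")
    s_to_i = _nonzero_map(f, sensory, interneurons)
    i_to_t = _nonzero_map(f, interneurons, targets)
    i_to_i = _nonzero_map(f, interneurons, interneurons) if max_layers == 2 else {}
    records: list[tuple[str, str, str, float]] = []
    for s, firsts in s_to_i.items():
        for i1, f1 in firsts.items():
            for t, f2 in i_to_t.get(i1, {}).items():
                records.append((s, t, i1, f1 * f2))
            if max_layers == 2:
                for i2, f12 in i_to_i.get(i1, {}).items():
                    if i2 == i1:
                        continue  # autapse fraction would revisit the neuron
                    for t, f2 in i_to_t.get(i2, {}).items():
                        records.append((s, t, f"{i1};{i2}", f1 * f12 * f2))
    return _as_table(records)


def _as_table(records: list[tuple[str, str, str, float]]) -> pd.DataFrame:
    df = pd.DataFrame(records, columns=PATHWAY_COLUMNS).astype(
        {"source": str, "target": str, "via": str, "score": float})
    return df.sort_values(PATHWAY_COLUMNS[:3], ignore_index=True)


def sensory_fingerprint(f: pd.DataFrame, interneuron: str,
                        sensory: Sequence[str],
                        modality: Mapping[str, str]) -> pd.Series:
    """Per-modality sensory input fractions of one interneuron (its 'sensory
    composition'): sum of f[s, interneuron] over sensory s of each modality."""
    missing = [s for s in sensory if s not in modality]
    if missing:
        raise ValueError(f"sensory neurons lacking modality: {missing}")
    hop = _nonzero_map(f, sensory, [interneuron])
    sums: dict[str, float] = {m: 0.0 for m in sorted(set(modality[s] for s in sensory))}
    for s, tv in hop.items():
        sums[modality[s]] += tv.get(interneuron, 0.0)
    return pd.Series(sums, name=interneuron)


def modality_rollup(scores: pd.DataFrame, modality: Mapping[str, str],
                    target_group: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Full pathway weights per (target, modality).

    ``scores`` concatenates direct and indirect PathwayScore tables (direct
    rows have an empty ``via``). Returns columns direct, indirect,
    total (= direct + indirect) and normalized_percent (total rescaled to sum
    to 100 over modalities per target; undefined and logged when every total
    is zero). ``target_group`` optionally maps neuron ids onto cluster-level
    targets before aggregation.
    """
    missing = sorted(set(scores["source"]) - set(modality))
    if missing:
        raise ValueError(f"pathway sources lacking modality: {missing}")
    df = scores.copy()
    df["modality"] = df["source"].map(modality)
    if target_group is not None:
        df["target"] = df["target"].map(lambda t: target_group.get(t, t))
    df["kind"] = np.where(df["via"] == "", "direct", "indirect")
    agg = (df.pivot_table(index=["target", "modality"], columns="kind",
                          values="score", aggfunc="sum", fill_value=0.0)
           .reindex(columns=["direct", "indirect"], fill_value=0.0)
           .reset_index())
    agg.columns.name = None
    agg["total"] = agg["direct"] + agg["indirect"]
    out = []
    for target, grp in agg.groupby("target", sort=True):
        grp = grp.copy()
        tot = grp["total"].sum()
        if tot > 0:
            grp["normalized_percent"] = 100.0 * grp["total"] / tot
        else:
            logger.warning("modality_rollup: all-zero totals for target %s; "
                           "normalized_percent undefined", target)
            grp["normalized_percent"] = np.nan
        out.append(grp)
    result = pd.concat(out, ignore_index=True) if out else agg.assign(
        normalized_percent=np.nan)
    return result.sort_values(["target", "modality"], ignore_index=True)


def dominant_modality(rollup: pd.DataFrame, target: str) -> str:
    """Modality with the largest total pathway weight onto ``target``; ties
    broken lexicographically (and logged)."""
    sub = rollup[rollup["target"] == target]
    if sub.empty:
        raise KeyError(f"no pathway weights for target {target!r}")
    best = sub["total"].max()
    winners = sorted(sub.loc[sub["total"] == best, "modality"])
    if len(winners) > 1:
        logger.info("dominant_modality(%s): tie among %s broken "
                    "lexicographically", target, winners)
    return winners[0]
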