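"""Synapse bookkeeping for a polyadic EM connectome.

The unit record is the *connector*: one presynaptic release site that may
contact several postsynaptic partners (polyadic). On disk a connector table
is a TSV with one row per (connector, postsynaptic partner) pair; a row with
an empty ``post_neuron`` is a *peripheral active zone* — a presynaptic-like
site without identifiable partners, annotated with the tissue it abuts.

Counting convention: a polyadic connector with k postsynaptic partners
contributes k synaptic pairs. Input fractions divide each (pre, post) count
by the post neuron's *total* input count over the whole connector table —
the neuron's full input budget, including partners outside any analysis
subset. Columns with zero total inputs are undefined (NaN), never zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CELL_CLASSES = {"sensory", "interneuron", "motor", "modulatory", "secretory", "tissue"}

CONNECTOR_COLUMNS = ["connector_id", "pre_neuron", "pre_node", "post_neuron",
                     "post_node", "region", "tissue_tag"]
ANNOTATION_COLUMNS = ["neuron_id", "cell_class", "cluster", "hemisphere", "modality"]


# ---------------------------------------------------------------------------
# table I/O and validation


def read_connectors(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={
        "connector_id": str, "pre_neuron": str, "post_neuron": str,
        "region": str, "tissue_tag": str})
    missing = set(CONNECTOR_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"connector table {path}: missing columns {sorted(missing)}")
    return validate_connectors(df)


def validate_connectors(df: pd.DataFrame) -> pd.DataFrame:
    """Check the peripheral-active-zone invariant: an empty-post row must
    carry a tissue_tag."""
    peripheral = df["post_neuron"].isna()
    untagged = peripheral & df["tissue_tag"].isna()
    if untagged.any():
        bad = df.loc[untagged, "connector_id"].tolist()
        raise ValueError(
            f"peripheral active zones without tissue_tag: connectors {bad}")
    return df


def read_annotations(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(ANNOTATION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"annotation table {path}: missing columns {sorted(missing)}")
    return validate_annotations(df)


def validate_annotations(df: pd.DataFrame) -> pd.DataFrame:
    if df["neuron_id"].duplicated().any():
        dupes = df.loc[df["neuron_id"].duplicated(), "neuron_id"].tolist()
        raise ValueError(f"duplicate neuron ids in annotations: {dupes}")
    bad_class = set(df["cell_class"]) - CELL_CLASSES
    if bad_class:
        raise ValueError(f"unknown cell classes: {sorted(bad_class)}")
    if df["cluster"].isna().any() or df["hemisphere"].isna().any():
        raise ValueError("cluster and hemisphere must be non-empty for every neuron")
    bad_hemi = set(df["hemisphere"]) - {"L", "R", "unpaired"}
    if bad_hemi:
        raise ValueError(f"hemisphere must be L, R or unpaired; got {sorted(bad_hemi)}")
    sensory = df["cell_class"] == "sensory"
    if df.loc[sensory, "modality"].isna().any():
        bad = df.loc[sensory & df["modality"].isna(), "neuron_id"].tolist()
        raise ValueError(f"sensory neurons lacking modality: {bad}")
    if df.loc[~sensory, "modality"].notna().any():
        bad = df.loc[~sensory & df["modality"].notna(), "neuron_id"].tolist()
        raise ValueError(f"non-sensory neurons carrying modality: {bad}")
    return df


def write_connectors(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, columns=CONNECTOR_COLUMNS)


def write_annotations(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, columns=ANNOTATION_COLUMNS)


def synapse_pairs(connectors: pd.DataFrame) -> pd.DataFrame:
    """Rows that are actual (pre, post) synaptic pairs (drops peripheral
    active zones)."""
    return connectors[connectors["post_neuron"].notna()]


def peripheral_zones(connectors: pd.DataFrame) -> pd.DataFrame:
    return connectors[connectors["post_neuron"].isna()]


# ---------------------------------------------------------------------------
# matrices


def build_counts(connectors: pd.DataFrame, neurons: pd.DataFrame) -> pd.DataFrame:
    """Monosynaptic count matrix: entry (i, j) = number of (pre=i, post=j)
    synaptic pairs. Rows/columns are indexed by every annotated neuron, in
    annotation order. Pairs referencing unannotated neurons are logged and
    dropped.
    """
    ids = list(neurons["neuron_id"])
    known = set(ids)
    pairs = synapse_pairs(connectors)
    unknown_mask = ~pairs["pre_neuron"].isin(known) | ~pairs["post_neuron"].isin(known)
    if unknown_mask.any():
        unknown_ids = sorted(
            set(pairs.loc[unknown_mask, "pre_neuron"]) |
            set(pairs.loc[unknown_mask, "post_neuron"]) - known)
        unknown_ids = [u for u in unknown_ids if u not in known]
        logger.warning("build_counts: dropping %d pairs touching unannotated "
                       "neurons %s", int(unknown_mask.sum()), unknown_ids)
        pairs = pairs[~unknown_mask]
    mat = pd.DataFrame(0, index=pd.Index(ids, name="pre"),
                       columns=pd.Index(ids, name="post"), dtype=int)
    if len(pairs):
        tallied = pairs.groupby(["pre_neuron", "post_neuron"]).size()
        for (pre, post), n in tallied.items():
            mat.loc[pre, post] = int(n)
    return mat


def input_fractions(counts: pd.DataFrame) -> pd.DataFrame:
    """Normalize each column by the post neuron's total input count.

    Columns whose total is zero become all-NaN (undefined), and are logged;
    they are never silently zero.
    """
    totals = counts.sum(axis=0)
    frac = counts.astype(float)
    zero = totals == 0
    if zero.any():
        logger.info("input_fractions: %d neurons with zero inputs -> undefined "
                    "columns: %s", int(zero.sum()), list(totals.index[zero])[:20])
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = frac.div(totals.where(~zero), axis=1)
    return frac


def aggregate_by_cluster(mat: pd.DataFrame, neurons: pd.DataFrame,
                         percent_of_out: bool = False) -> pd.DataFrame:
    """Collapse a neuron-level matrix into cluster blocks by summation.

    With ``percent_of_out`` each source cluster's row is expressed as the
    percentage of that cluster's total outgoing budget.
    """
    cluster = neurons.set_index("neuron_id")["cluster"]
    missing = [i for i in mat.index if i not in cluster.index]
    if missing:
        raise ValueError(f"neurons without cluster annotation: {missing}")
    out = mat.groupby(cluster.reindex(mat.index).values, sort=True).sum()
    out = out.T.groupby(cluster.reindex(mat.columns).values, sort=True).sum().T
    out.index.name, out.columns.name = "pre_cluster", "post_cluster"
    if percent_of_out:
        row_tot = out.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            out = out.div(row_tot.where(row_tot > 0), axis=0) * 100.0
    return out


# ---------------------------------------------------------------------------
# balance, budgets, tallies


@dataclass(frozen=True)
class IoBalance:
    neuron_id: str
    inputs: int
    outputs: int

    @property
    def input_share(self) -> float | None:
        """in / (in + out); None when the neuron has no synapses in scope."""
        tot = self.inputs + self.outputs
        return None if tot == 0 else self.inputs / tot


def io_balance(neuron_id: str, connectors: pd.DataFrame,
               region: str | None = None) -> IoBalance:
    """Input/output synapse balance of one neuron, optionally restricted to
    connectors carrying a region label (e.g. 'CNS')."""
    pairs = synapse_pairs(connectors)
    if region is not None:
        pairs = pairs[pairs["region"] == region]
    inputs = int((pairs["post_neuron"] == neuron_id).sum())
    outputs = int((pairs["pre_neuron"] == neuron_id).sum())
    return IoBalance(neuron_id, inputs, outputs)


@dataclass(frozen=True)
class HemisphereBudget:
    """Synapse-pair tallies of one cluster by origin x target hemisphere.

    ``direction`` 'in' counts pairs whose post neuron is in the cluster,
    'out' pairs whose pre neuron is; origin hemisphere is always the pre
    neuron's, target the post neuron's. Only L/R-paired neurons on both ends
    count; ``excluded_unpaired`` reports the pairs dropped for involving an
    unpaired neuron.
    """

    cluster: str
    direction: str
    LL: int
    RR: int
    LR: int
    RL: int
    excluded_unpaired: int = 0

    @property
    def total(self) -> int:
        return self.LL + self.RR + self.LR + self.RL

    def percentages(self) -> dict[str, float] | None:
        if self.total == 0:
            return None
        return {k: 100.0 * getattr(self, k) / self.total
                for k in ("LL", "RR", "LR", "RL")}


def hemisphere_budgets(connectors: pd.DataFrame, neurons: pd.DataFrame,
                       cluster: str, direction: str) -> HemisphereBudget:
    if direction not in ("in", "out"):
        raise ValueError(f"direction must be 'in' or 'out', got {direction!r}")
    if cluster not in set(neurons["cluster"]):
        raise KeyError(f"unknown cluster {cluster!r}")
    hemi = neurons.set_index("neuron_id")["hemisphere"]
    members = set(neurons.loc[neurons["cluster"] == cluster, "neuron_id"])
    pairs = synapse_pairs(connectors)
    anchor = "post_neuron" if direction == "in" else "pre_neuron"
    pairs = pairs[pairs[anchor].isin(members)]
    pre_h = pairs["pre_neuron"].map(hemi)
    post_h = pairs["post_neuron"].map(hemi)
    paired = pre_h.isin(["L", "R"]) & post_h.isin(["L", "R"])
    excluded = int((~paired).sum())
    if excluded:
        logger.info("hemisphere_budgets(%s, %s): excluded %d pairs involving "
                    "unpaired neurons", cluster, direction, excluded)
    key = pre_h[paired] + post_h[paired]
    tallies = key.value_counts()
    return HemisphereBudget(
        cluster=cluster, direction=direction,
        LL=int(tallies.get("LL", 0)), RR=int(tallies.get("RR", 0)),
        LR=int(tallies.get("LR", 0)), RL=int(tallies.get("RL", 0)),
        excluded_unpaired=excluded)


def peripheral_zone_tally(connectors: pd.DataFrame) -> pd.DataFrame:
    """Per-neuron, per-tissue counts of peripheral active zones.

    The grand total equals the number of empty-post connector rows; an
    untagged empty-post row is a validation error.
    """
    zones = peripheral_zones(connectors)
    untagged = zones["tissue_tag"].isna()
    if untagged.any():
        bad = zones.loc[untagged, "connector_id"].tolist()
        raise ValueError(
            f"peripheral active zones without tissue_tag: connectors {bad}")
    if zones.empty:
        return pd.DataFrame(columns=["neuron_id", "tissue_tag", "n"])
    tally = (zones.groupby(["pre_neuron", "tissue_tag"]).size()
             .rename("n").reset_index()
             .rename(columns={"pre_neuron": "neuron_id"}))
    return tally
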