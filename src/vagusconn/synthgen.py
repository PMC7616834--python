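"""Seeded generators for synthetic connectomes and peristalsis traces.

The circuit generator emulates the structure of a bilateral, clustered,
layered enteric circuit: mirrored left/right neuron clusters (sensory with a
modality, interneuron layers, motor, modulatory), polyadic connectors,
random-walk tree skeletons with a designated origin node, and peripheral
active zones on modulatory neurons tagged by target tissue. Every stochastic
draw flows from a single integer seed, and the generator returns an exact
ground-truth bundle (counts, fractions, pathway sums by exhaustive
enumeration, hemisphere budgets, tissue tallies) against which the analysis
modules can be checked.

Hemisphere asymmetry: connection probabilities of left-origin neurons are
scaled by (1 + eps) and right-origin by (1 - eps), so the expected
ipsilateral asymmetry index is 100 * eps.

The trace generator emulates a two-ROI recording of triggered peristalsis:
triggers follow a Poisson process with a physiological refractory period
(contraction waves cannot overlap), each trigger completes with a fixed
probability producing a delayed myogenic bump, and both channels carry
exponential-decay event kernels plus Gaussian noise.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .circuit import (ANNOTATION_COLUMNS, CONNECTOR_COLUMNS, CELL_CLASSES)
from .physiology import TwoRoiTrace, write_trace
from .skeletons import Skeleton, SkeletonNode, write_swc

logger = logging.getLogger(__name__)

DEFAULT_TISSUE_TAGS = {"HCG": 0.4, "PVG": 0.3, "ring_gland": 0.2, "midgut": 0.1}


@dataclass
class ClusterSpec:
    label: str
    cell_class: str
    n_per_hemisphere: int
    modality: str | None = None
    unpaired: bool = False  # single unpaired population of size n_per_hemisphere


@dataclass
class EdgeSpec:
    source: str
    target: str
    p_connect: float  # base probability a (pre, post) neuron pair is connected
    mean_pairs: float = 1.0  # mean synapse pairs per connected pair (>= 1)
    p_ipsi: float = 0.85  # probability mass on ipsilateral connections
    region: str = "CNS"


@dataclass
class SkeletonSpec:
    n_nodes: int = 40
    step_nm: float = 1000.0
    branch_prob: float = 0.1


@dataclass
class CircuitConfig:
    seed: int
    clusters: list[ClusterSpec]
    edges: list[EdgeSpec]
    asymmetry_eps: float = 0.0
    polyadicity: float = 1.5  # mean postsynaptic partners per connector
    skeleton: SkeletonSpec = field(default_factory=SkeletonSpec)
    peripheral_zone_rate: float = 3.0  # zones per modulatory neuron
    tissue_tags: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TISSUE_TAGS))

    def validate(self) -> None:
        labels = [c.label for c in self.clusters]
        if len(set(labels)) != len(labels):
            raise ValueError("cluster labels must be unique")
        for c in self.clusters:
            if c.cell_class not in CELL_CLASSES:
                raise ValueError(f"cluster {c.label}: unknown cell class "
                                 f"{c.cell_class!r}")
            if c.n_per_hemisphere <= 0:
                raise ValueError(f"cluster {c.label}: size must be positive")
            if (c.modality is None) == (c.cell_class == "sensory"):
                raise ValueError(f"cluster {c.label}: modality required iff sensory")
        if not -1.0 <= self.asymmetry_eps <= 1.0:
            raise ValueError("asymmetry_eps must be in [-1, 1]")
        if self.polyadicity < 1.0:
            raise ValueError("polyadicity must be >= 1")
        if self.peripheral_zone_rate < 0:
            raise ValueError("peripheral_zone_rate must be >= 0")
        probs = np.array(list(self.tissue_tags.values()), dtype=float)
        if len(probs) == 0 or abs(probs.sum() - 1.0) > 1e-9 or (probs < 0).any():
            raise ValueError("tissue_tags must be a probability distribution")
        if self.skeleton.n_nodes < 1 or self.skeleton.step_nm <= 0:
            raise ValueError("skeleton spec: n_nodes >= 1 and step_nm > 0")
        for e in self.edges:
            if e.source not in labels or e.target not in labels:
                raise ValueError(f"edge {e.source}->{e.target}: unknown cluster")
            if not 0.0 <= e.p_connect <= 1.0 or not 0.0 <= e.p_ipsi <= 1.0:
                raise ValueError(f"edge {e.source}->{e.target}: probability "
                                 "out of [0, 1]")
            if e.mean_pairs < 1.0 and e.p_connect > 0:
                raise ValueError(f"edge {e.source}->{e.target}: mean_pairs "
                                 "must be >= 1")
            worst = e.p_connect * 2 * max(e.p_ipsi, 1 - e.p_ipsi) \
                * (1 + abs(self.asymmetry_eps))
            if worst > 1.0:
                raise ValueError(
                    f"edge {e.source}->{e.target}: effective connection "
                    f"probability {worst:.3f} exceeds 1; lower p_connect")


@dataclass
class SimulatedCircuit:
    config: CircuitConfig
    skeletons: dict[str, Skeleton]
    connectors: pd.DataFrame
    annotations: pd.DataFrame
    truth: dict

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        """Write SWC files + manifest, connector and annotation TSVs, and the
        ground-truth JSON. Returns the paths written."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        swc_dir = out_dir / "skeletons"
        swc_dir.mkdir(exist_ok=True)
        manifest_rows = []
        for nid in sorted(self.skeletons):
            s = self.skeletons[nid]
            fname = f"{nid}.swc"
            write_swc(s, swc_dir / fname)
            manifest_rows.append({"neuron_id": nid,
                                  "swc_path": f"skeletons/{fname}",
                                  "origin_node": s.origin_node})
        paths = {
            "manifest": out_dir / "skeletons.tsv",
            "connectors": out_dir / "connectors.tsv",
            "annotations": out_dir / "annotations.tsv",
            "truth": out_dir / "ground_truth.json",
        }
        pd.DataFrame(manifest_rows).to_csv(paths["manifest"], sep="\t", index=False)
        self.connectors.to_csv(paths["connectors"], sep="\t", index=False,
                               columns=CONNECTOR_COLUMNS)
        self.annotations.to_csv(paths["annotations"], sep="\t", index=False,
                                columns=ANNOTATION_COLUMNS)
        with open(paths["truth"], "w") as fh:
            json.dump(_jsonable(self.truth), fh, indent=1, sort_keys=True)
        return paths


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


# ---------------------------------------------------------------------------
# circuit generation


def _random_walk_skeleton(rng: np.random.Generator, neuron_id: str,
                          spec: SkeletonSpec) -> Skeleton:
    """Random-walk tree: each new node extends the previous one, or with
    ``branch_prob`` sprouts from a uniformly chosen earlier node. Root is the
    designated origin node."""
    nodes: dict[int, SkeletonNode] = {
        1: SkeletonNode(1, None, 0.0, 0.0, 0.0, 100.0)}
    pos = {1: np.zeros(3)}
    for i in range(2, spec.n_nodes + 1):
        if i > 2 and rng.random() < spec.branch_prob:
            parent = int(rng.integers(1, i))
        else:
            parent = i - 1
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        p = pos[parent] + spec.step_nm * direction
        pos[i] = p
        nodes[i] = SkeletonNode(i, parent, float(p[0]), float(p[1]),
                                float(p[2]), 50.0)
    return Skeleton(neuron_id, nodes, origin_node=1)


def _neuron_table(config: CircuitConfig) -> pd.DataFrame:
    rows = []
    for c in config.clusters:
        hemis = ["unpaired"] if c.unpaired else ["L", "R"]
        for h in hemis:
            for k in range(1, c.n_per_hemisphere + 1):
                rows.append({
                    "neuron_id": f"{c.label}.{h}{k}",
                    "cell_class": c.cell_class, "cluster": c.label,
                    "hemisphere": h, "modality": c.modality})
    return pd.DataFrame(rows, columns=ANNOTATION_COLUMNS)


def generate_circuit(config: CircuitConfig) -> SimulatedCircuit:
    """Generate skeletons, a polyadic connector table, annotations and the
    exact ground-truth bundle. Deterministic for a given seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    neurons = _neuron_table(config)
    hemi = neurons.set_index("neuron_id")["hemisphere"].to_dict()

    skeletons = {nid: _random_walk_skeleton(rng, nid, config.skeleton)
                 for nid in neurons["neuron_id"]}

    by_cluster = {c.label: list(
        neurons.loc[neurons["cluster"] == c.label, "neuron_id"])
        for c in config.clusters}
    eps = config.asymmetry_eps

    # draw synapse-pair counts per (pre, post) neuron pair
    pair_counts: dict[tuple[str, str, str], int] = {}  # (pre, post, region) -> n
    for e in config.edges:
        for pre in by_cluster[e.source]:
            h_pre = hemi[pre]
            asym = {"L": 1 + eps, "R": 1 - eps}.get(h_pre, 1.0)
            for post in by_cluster[e.target]:
                if post == pre:
                    continue
                h_post = hemi[post]
                if h_pre in ("L", "R") and h_post in ("L", "R"):
                    lateral = 2 * e.p_ipsi if h_pre == h_post else 2 * (1 - e.p_ipsi)
                else:
                    lateral = 1.0
                w = e.p_connect * lateral * asym
                if rng.random() < w:
                    n = 1 + int(rng.poisson(e.mean_pairs - 1.0))
                    key = (pre, post, e.region)
                    pair_counts[key] = pair_counts.get(key, 0) + n

    # group pairs into polyadic connectors per (pre neuron, region)
    rows = []
    connector_seq = 0
    per_pre: dict[tuple[str, str], list[str]] = {}
    for (pre, post, region), n in pair_counts.items():
        per_pre.setdefault((pre, region), []).extend([post] * n)
    for (pre, region) in sorted(per_pre):
        partners = per_pre[(pre, region)]
        rng.shuffle(partners)
        skel_pre = skeletons[pre]
        idx = 0
        while idx < len(partners):
            k = 1 + int(rng.poisson(config.polyadicity - 1.0))
            chunk = partners[idx:idx + k]
            idx += k
            connector_seq += 1
            cid = f"cn{connector_seq:06d}"
            pre_node = int(rng.choice(sorted(skel_pre.nodes)))
            for post in chunk:
                post_node = int(rng.choice(sorted(skeletons[post].nodes)))
                rows.append({"connector_id": cid, "pre_neuron": pre,
                             "pre_node": pre_node, "post_neuron": post,
                             "post_node": post_node, "region": region,
                             "tissue_tag": None})

    # peripheral active zones on modulatory neurons
    tissue_labels = sorted(config.tissue_tags)
    tissue_p = np.array([config.tissue_tags[t] for t in tissue_labels])
    zone_truth: dict[str, dict[str, int]] = {}
    for nid in neurons.loc[neurons["cell_class"] == "modulatory", "neuron_id"]:
        n_zones = int(rng.poisson(config.peripheral_zone_rate))
        tallies: dict[str, int] = {}
        for _ in range(n_zones):
            tag = str(rng.choice(tissue_labels, p=tissue_p))
            tallies[tag] = tallies.get(tag, 0) + 1
            connector_seq += 1
            rows.append({"connector_id": f"cn{connector_seq:06d}",
                         "pre_neuron": nid,
                         "pre_node": int(rng.choice(sorted(skeletons[nid].nodes))),
                         "post_neuron": None, "post_node": None,
                         "region": "periphery", "tissue_tag": tag})
        if tallies:
            zone_truth[nid] = tallies

    connectors = pd.DataFrame(rows, columns=CONNECTOR_COLUMNS)
    truth = _ground_truth(config, neurons, pair_counts, zone_truth)
    return SimulatedCircuit(config, skeletons, connectors, neurons, truth)


def _ground_truth(config: CircuitConfig, neurons: pd.DataFrame,
                  pair_counts: dict[tuple[str, str, str], int],
                  zone_truth: dict) -> dict:
    """Exact expected analysis outputs, computed straight from the planted
    pair counts by enumeration, independently of the analysis modules."""
    counts: dict[tuple[str, str], int] = {}
    for (pre, post, _region), n in pair_counts.items():
        counts[(pre, post)] = counts.get((pre, post), 0) + n
    in_total: dict[str, int] = {}
    out_total: dict[str, int] = {}
    for (pre, post), n in counts.items():
        in_total[post] = in_total.get(post, 0) + n
        out_total[pre] = out_total.get(pre, 0) + n
    fractions = {(pre, post): n / in_total[post]
                 for (pre, post), n in counts.items()}

    hemi = neurons.set_index("neuron_id")["hemisphere"].to_dict()
    cluster = neurons.set_index("neuron_id")["cluster"].to_dict()
    budgets: dict[tuple[str, str], dict[str, int]] = {}
    for (pre, post), n in counts.items():
        hp, hq = hemi[pre], hemi[post]
        if hp not in ("L", "R") or hq not in ("L", "R"):
            continue
        key = hp + hq
        for anchor, direction in ((cluster[post], "in"), (cluster[pre], "out")):
            b = budgets.setdefault((anchor, direction),
                                   {"LL": 0, "RR": 0, "LR": 0, "RL": 0})
            b[key] += n

    # exhaustive layered simple-path enumeration (independent of pathways.py)
    cls = neurons.set_index("neuron_id")["cell_class"].to_dict()
    sensory = [n for n in cls if cls[n] == "sensory"]
    inter = [n for n in cls if cls[n] == "interneuron"]
    targets = [n for n in cls
               if cls[n] in ("modulatory", "motor", "secretory")]
    frac = fractions

    def f(a, b):
        return frac.get((a, b), 0.0)

    pathway_sums: dict[tuple[str, str], dict[str, float]] = {}
    for s in sensory:
        for t in targets:
            direct = f(s, t)
            indirect = 0.0
            for i1 in inter:
                f1 = f(s, i1)
                if f1 == 0.0:
                    continue
                indirect += f1 * f(i1, t)
                for i2 in inter:
                    if i2 == i1:
                        continue
                    f12 = f(i1, i2)
                    if f12:
                        indirect += f1 * f12 * f(i2, t)
            if direct or indirect:
                pathway_sums[(s, t)] = {"direct": direct, "indirect": indirect}

    return {
        "counts": {f"{a}->{b}": n for (a, b), n in sorted(counts.items())},
        "in_total": in_total,
        "out_total": out_total,
        "fractions": {f"{a}->{b}": v for (a, b), v in sorted(fractions.items())},
        "hemisphere_budgets": {f"{c}:{d}": b
                               for (c, d), b in sorted(budgets.items())},
        "pathway_sums": {f"{s}->{t}": v
                         for (s, t), v in sorted(pathway_sums.items())},
        "peripheral_zone_tally": zone_truth,
        "total_pairs": int(sum(counts.values())),
    }


def default_demo_config(seed: int) -> CircuitConfig:
    """Reduced-scale cast of the enteric swallowing circuit: mirrored
    esophageal/proventricular sensory clusters, two interneuron layers,
    ring-muscle motor neurons, and serotonergic modulatory neurons carrying
    peripheral active zones."""
    clusters = [
        ClusterSpec("EG_ant", "sensory", 3, modality="ENS_mechano"),
        ClusterSpec("EG_med", "sensory", 3, modality="ENS_mechano"),
        ClusterSpec("EG_post", "sensory", 4, modality="ENS_mechano"),
        ClusterSpec("PVG_sens", "sensory", 3, modality="ENS_chemo"),
        ClusterSpec("Aorta_sens", "sensory", 2, modality="ENS_mechano",
                    unpaired=True),
        ClusterSpec("L1", "interneuron", 4),
        ClusterSpec("L2", "interneuron", 3),
        ClusterSpec("ERM_motor", "motor", 3),
        ClusterSpec("Se0_ens", "modulatory", 2),
    ]
    edges = [
        EdgeSpec("EG_post", "Se0_ens", 0.4, 3.0),
        EdgeSpec("PVG_sens", "Se0_ens", 0.15, 1.5),
        EdgeSpec("EG_ant", "L1", 0.35, 2.0),
        EdgeSpec("EG_med", "L1", 0.35, 2.0),
        EdgeSpec("EG_post", "L1", 0.4, 2.0),
        EdgeSpec("PVG_sens", "L1", 0.3, 2.0),
        EdgeSpec("Aorta_sens", "L1", 0.3, 1.5),
        EdgeSpec("L1", "L2", 0.3, 2.0),
        EdgeSpec("L1", "Se0_ens", 0.35, 2.0),
        EdgeSpec("L2", "Se0_ens", 0.35, 2.0),
        EdgeSpec("EG_med", "ERM_motor", 0.3, 2.0),
        EdgeSpec("ERM_motor", "EG_post", 0.35, 2.0),
    ]
    return CircuitConfig(seed=seed, clusters=clusters, edges=edges,
                         asymmetry_eps=0.05, polyadicity=1.5)


# ---------------------------------------------------------------------------
# trace generation


@dataclass
class TraceConfig:
    seed: int
    duration_s: float = 600.0
    sampling_rate: float = 20.0
    trigger_rate_per_min: float = 6.0
    completion_prob: float = 0.7
    latency_s: float = 0.5
    kernel_tau_s: float = 0.8
    noise_sd: float = 0.05  # fraction of event amplitude
    refractory_s: float = 2.0  # contraction waves cannot overlap
    n_triggers: int | None = None  # exact trigger count (overrides duration)

    def validate(self) -> None:
        for name in ("duration_s", "sampling_rate", "trigger_rate_per_min",
                     "latency_s", "kernel_tau_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 <= self.completion_prob <= 1.0:
            raise ValueError("completion_prob must be in [0, 1]")
        if self.noise_sd < 0 or self.refractory_s < 0:
            raise ValueError("noise_sd and refractory_s must be >= 0")
        mean_gap = 60.0 / self.trigger_rate_per_min
        if self.refractory_s >= mean_gap:
            raise ValueError("refractory period exceeds mean inter-trigger "
                             "interval; lower trigger_rate_per_min")
        if self.latency_s >= mean_gap:
            logger.warning("latency >= mean inter-trigger interval; "
                           "trigger/completion pairing may be ambiguous")


def generate_trace(config: TraceConfig) -> tuple[TwoRoiTrace, dict]:
    """Simulate a two-ROI peristalsis recording with planted ground truth.

    Triggers arrive as a refractory Poisson process at ``trigger_rate_per_min``;
    each completes with ``completion_prob``, placing an ROI2 bump
    ``latency_s`` later. Events are unit-amplitude exponential-decay kernels
    (time constant ``kernel_tau_s``) on a zero baseline plus Gaussian noise of
    ``noise_sd`` amplitude fractions. Returns the trace and a dict with the
    exact trigger times, completion flags and ROI2 event times.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    mean_gap = 60.0 / config.trigger_rate_per_min
    exp_scale = mean_gap - config.refractory_s  # exponential part of each gap

    triggers: list[float] = []
    t_cur = 2.0 + rng.exponential(exp_scale)
    if config.n_triggers is not None:
        while len(triggers) < config.n_triggers:
            triggers.append(t_cur)
            t_cur += config.refractory_s + rng.exponential(exp_scale)
        duration = triggers[-1] + 5 * config.kernel_tau_s + config.latency_s
    else:
        duration = config.duration_s
        while t_cur < duration - config.latency_s - config.kernel_tau_s:
            triggers.append(t_cur)
            t_cur += config.refractory_s + rng.exponential(exp_scale)
    triggers_arr = np.asarray(triggers)
    completed = rng.random(len(triggers_arr)) < config.completion_prob
    roi2_times = triggers_arr[completed] + config.latency_s

    n = int(round(duration * config.sampling_rate)) + 1
    t = np.arange(n) / config.sampling_rate

    def kernel_sum(event_times: np.ndarray) -> np.ndarray:
        x = np.zeros(n)
        for te in event_times:
            i0 = int(np.ceil(te * config.sampling_rate))
            if i0 >= n:
                continue
            tail = t[i0:] - te
            x[i0:] += np.exp(-tail / config.kernel_tau_s)
        return x

    roi1 = kernel_sum(triggers_arr)
    roi2 = kernel_sum(roi2_times)
    if config.noise_sd > 0:
        roi1 = roi1 + rng.normal(0.0, config.noise_sd, n)
        roi2 = roi2 + rng.normal(0.0, config.noise_sd, n)

    trace = TwoRoiTrace(t, roi1, roi2, config.sampling_rate)
    truth = {
        "trigger_times": triggers_arr.tolist(),
        "completed_flags": completed.tolist(),
        "roi2_event_times": roi2_times.tolist(),
        "completion_rate_percent":
            100.0 * float(completed.sum()) / len(completed) if len(completed)
            else None,
        "duration_s": float(duration),
    }
    return trace, truth
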