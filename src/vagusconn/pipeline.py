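"""End-to-end pipeline: (optional) simulation, matrices, pathways, symmetry,
placement and physiology, with a reproducibility manifest.

A run is configured by a plain dict (typically loaded from YAML/JSON); the
same config and seed reproduce byte-identical outputs, recorded as SHA-256
digests in the run manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import pandas as pd
import yaml

from . import circuit, pathways, physiology, placement, symmetry, synthgen
from .skeletons import read_skeleton_manifest

logger = logging.getLogger("vagusconn")


class _WarningCounter(logging.Handler):
    def __init__(self) -> None:
        super().__init__(level=logging.WARNING)
        self.count = 0

    def emit(self, record: logging.LogRecord) -> None:
        self.count += 1


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path}: expected a mapping")
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _dump_json(obj, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True, allow_nan=True)
        fh.write("\n")


def simulate_inputs(config: dict, seed: int, out_dir: Path) -> dict[str, Path]:
    """Generate synthetic circuit + trace inputs under ``out_dir``/inputs."""
    syn = config.get("synthgen", {})
    ccfg = synthgen.default_demo_config(seed)
    for key in ("asymmetry_eps", "polyadicity", "peripheral_zone_rate"):
        if key in syn.get("circuit", {}):
            setattr(ccfg, key, syn["circuit"][key])
    sim = synthgen.generate_circuit(ccfg)
    input_dir = out_dir / "inputs"
    paths = sim.write(input_dir)
    tcfg = synthgen.TraceConfig(seed=seed, **syn.get("trace", {}))
    trace, truth = synthgen.generate_trace(tcfg)
    paths["trace"] = input_dir / "trace.csv"
    physiology.write_trace(trace, paths["trace"])
    _dump_json(truth, input_dir / "trace_truth.json")
    paths["trace_truth"] = input_dir / "trace_truth.json"
    return paths


def run_pipeline(config: dict, seed: int, out_dir: str | Path) -> dict:
    """Execute every stage and return the run manifest.

    Stages: simulate (when the config has a ``synthgen`` block) -> counts ->
    fractions -> pathways -> symmetry -> placement -> physiology (when a
    trace is available) -> report. Any stage validation error aborts with
    the stage name.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    counter = _WarningCounter()
    logger.addHandler(counter)
    stage = "configure"
    outputs: dict[str, Path] = {}
    try:
        # ---- inputs
        if "synthgen" in config:
            stage = "simulate"
            inputs = simulate_inputs(config, seed, out_dir)
        else:
            stage = "load-inputs"
            req = config.get("inputs", {})
            for key in ("connectors", "annotations"):
                if key not in req:
                    raise ValueError(f"config inputs missing {key!r} file")
            inputs = {k: Path(v) for k, v in req.items()}
            for k, p in inputs.items():
                if not p.exists():
                    raise FileNotFoundError(f"input {k!r}: no such file {p}")
        connectors = circuit.read_connectors(inputs["connectors"])
        neurons = circuit.read_annotations(inputs["annotations"])
        skeletons = None
        if "manifest" in inputs:
            skeletons = {s.neuron_id: s
                         for s in read_skeleton_manifest(inputs["manifest"])}

        # ---- counts and fractions
        stage = "counts"
        counts = circuit.build_counts(connectors, neurons)
        outputs["counts"] = out_dir / "counts.csv"
        counts.to_csv(outputs["counts"])
        stage = "fractions"
        fractions = circuit.input_fractions(counts)
        outputs["fractions"] = out_dir / "fractions.csv"
        fractions.to_csv(outputs["fractions"])
        cluster_pct = circuit.aggregate_by_cluster(counts, neurons,
                                                   percent_of_out=True)
        outputs["cluster_out_percent"] = out_dir / "cluster_out_percent.csv"
        cluster_pct.to_csv(outputs["cluster_out_percent"])

        # ---- pathways
        stage = "pathways"
        cls = neurons.set_index("neuron_id")["cell_class"]
        sensory = list(cls.index[cls == "sensory"])
        inter = list(cls.index[cls == "interneuron"])
        target_classes = config.get("pathways", {}).get(
            "target_classes", ["modulatory"])
        targets = list(cls.index[cls.isin(target_classes)])
        max_layers = int(config.get("pathways", {}).get("max_layers", 2))
        direct = pathways.direct_scores(fractions, sensory, targets)
        indirect = pathways.indirect_scores(fractions, sensory, inter,
                                            targets, max_layers=max_layers)
        scores = pd.concat([direct, indirect], ignore_index=True)
        outputs["pathway_scores"] = out_dir / "pathway_scores.csv"
        scores.to_csv(outputs["pathway_scores"], index=False)
        modality = neurons.set_index("neuron_id")["modality"].dropna().to_dict()
        if len(scores):
            rollup = pathways.modality_rollup(scores, modality)
        else:
            rollup = pd.DataFrame(columns=["target", "modality", "direct",
                                           "indirect", "total",
                                           "normalized_percent"])
        outputs["modality_weights"] = out_dir / "modality_weights.csv"
        rollup.to_csv(outputs["modality_weights"], index=False)

        # ---- symmetry
        stage = "symmetry"
        budgets = []
        paired_clusters = sorted(
            set(neurons.loc[neurons["hemisphere"].isin(["L", "R"]), "cluster"]))
        for cl in paired_clusters:
            for direction in ("in", "out"):
                budgets.append(circuit.hemisphere_budgets(
                    connectors, neurons, cl, direction))
        budgets = [b for b in budgets if b.total > 0]
        if budgets:
            sym_table, sym_summary = symmetry.symmetry_report(
                budgets, on=config.get("symmetry", {}).get("on", "percent"))
            outputs["symmetry"] = out_dir / "symmetry.csv"
            sym_table.to_csv(outputs["symmetry"], index=False)
            outputs["symmetry_summary"] = out_dir / "symmetry_summary.json"
            _dump_json(sym_summary, outputs["symmetry_summary"])

        # ---- placement
        if skeletons is not None:
            stage = "placement"
            cluster_map = neurons.set_index("neuron_id")["cluster"].to_dict()
            tables = []
            for nid in sorted(skeletons):
                rec = placement.synapse_distances(
                    skeletons[nid], connectors, partner_group=cluster_map)
                if len(rec):
                    tables.append(rec)
            if tables:
                placement_table = pd.concat(tables, ignore_index=True)
                outputs["placement"] = out_dir / "placement.csv"
                placement_table.to_csv(outputs["placement"], index=False)
                per_neuron = {}
                for nid, sub in placement_table.groupby("neuron"):
                    try:
                        summary, f_stat, p = placement.group_order_test(sub)
                        per_neuron[nid] = {
                            "groups": summary.to_dict(orient="records"),
                            "F": f_stat, "p": p}
                    except placement.InsufficientDataError as exc:
                        per_neuron[nid] = {"error": str(exc)}
                outputs["placement_summary"] = out_dir / "placement_summary.json"
                _dump_json(per_neuron, outputs["placement_summary"])

        # ---- physiology
        if "trace" in inputs:
            stage = "physiology"
            trace = physiology.read_trace(inputs["trace"])
            phys_cfg = config.get("physiology", {})
            summary = physiology.analyze_trace(
                trace,
                threshold_k=float(phys_cfg.get("threshold_k", 3.0)),
                min_interval=float(phys_cfg.get("min_interval", 1.0)),
                min_prominence=float(phys_cfg.get("min_prominence", 0.1)),
                window=float(phys_cfg.get("pairing_window", 2.0)))
            outputs["physiology_summary"] = out_dir / "physiology_summary.json"
            _dump_json(summary, outputs["physiology_summary"])

        # ---- report / manifest
        stage = "report"
        manifest = {
            "seed": seed,
            "config_hash": hashlib.sha256(
                json.dumps(config, sort_keys=True).encode()).hexdigest(),
            "inputs": {k: {"path": str(p), "sha256": _sha256(Path(p))}
                       for k, p in sorted(inputs.items()) if Path(p).is_file()},
            "outputs": {k: {"path": str(p), "sha256": _sha256(p)}
                        for k, p in sorted(outputs.items())},
            "warnings": counter.count,
        }
        manifest_path = out_dir / "manifest.json"
        _dump_json(manifest, manifest_path)
        return manifest
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    finally:
        logger.removeHandler(counter)
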