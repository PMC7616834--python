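"""Synthetic generators: determinism, planted ground truth, recoverability."""

import numpy as np
import pandas as pd
import pytest

from vagusconn import circuit, pathways
from vagusconn.physiology import analyze_trace, detect_events
from vagusconn.skeletons import read_swc
from vagusconn.synthgen import (CircuitConfig, ClusterSpec, EdgeSpec,
                                SkeletonSpec, TraceConfig,
                                default_demo_config, generate_circuit,
                                generate_trace)


def small_config(seed, **overrides):
    cfg = CircuitConfig(
        seed=seed,
        clusters=[ClusterSpec("S", "sensory", 3, modality="mechano"),
                  ClusterSpec("I", "interneuron", 3),
                  ClusterSpec("T", "modulatory", 2)],
        edges=[EdgeSpec("S", "I", 0.4, 2.0), EdgeSpec("I", "T", 0.4, 2.0),
               EdgeSpec("S", "T", 0.2, 1.5)],
        skeleton=SkeletonSpec(n_nodes=12),
        peripheral_zone_rate=2.0)
    for k, v in overrides.items():
        setattr(cfg, k, v)
    return cfg


class TestGenerateCircuit:
    def test_same_seed_reproduces_byte_identical_outputs(self, tmp_path):
        d1, d2 = tmp_path / "r1", tmp_path / "r2"
        generate_circuit(small_config(7)).write(d1)
        generate_circuit(small_config(7)).write(d2)
        for rel in ("connectors.tsv", "annotations.tsv", "ground_truth.json",
                    "skeletons.tsv"):
            assert (d1 / rel).read_bytes() == (d2 / rel).read_bytes()
        for swc in sorted((d1 / "skeletons").iterdir()):
            assert swc.read_bytes() == \
                (d2 / "skeletons" / swc.name).read_bytes()

    def test_zero_probability_edges_give_empty_synapses(self):
        cfg = small_config(3, peripheral_zone_rate=0.0)
        for e in cfg.edges:
            e.p_connect = 0.0
        sim = generate_circuit(cfg)
        assert len(sim.connectors) == 0
        assert sim.truth["total_pairs"] == 0

    def test_counts_matrix_matches_planted_ground_truth(self):
        sim = generate_circuit(small_config(11))
        m = circuit.build_counts(sim.connectors, sim.annotations)
        for key, n in sim.truth["counts"].items():
            pre, post = key.split("->")
            assert m.loc[pre, post] == n
        assert int(m.to_numpy().sum()) == sim.truth["total_pairs"]

    def test_budgets_match_planted_tallies(self):
        sim = generate_circuit(small_config(5))
        for key, want in sim.truth["hemisphere_budgets"].items():
            cl, direction = key.split(":")
            b = circuit.hemisphere_budgets(sim.connectors, sim.annotations,
                                           cl, direction)
            assert {"LL": b.LL, "RR": b.RR, "LR": b.LR, "RL": b.RL} == want

    def test_peripheral_tally_matches_ground_truth(self):
        sim = generate_circuit(small_config(9))
        tally = circuit.peripheral_zone_tally(sim.connectors)
        got = {(r.neuron_id, r.tissue_tag): r.n
               for r in tally.itertuples(index=False)}
        want = {(nid, tag): n
                for nid, tags in sim.truth["peripheral_zone_tally"].items()
                for tag, n in tags.items()}
        assert got == want

    def test_pathway_sums_cross_check_against_pipeline(self):
        sim = generate_circuit(small_config(13))
        m = circuit.build_counts(sim.connectors, sim.annotations)
        f = circuit.input_fractions(m)
        cls = sim.annotations.set_index("neuron_id")["cell_class"]
        sensory = list(cls.index[cls == "sensory"])
        inter = list(cls.index[cls == "interneuron"])
        targets = list(cls.index[cls == "modulatory"])
        table = pd.concat([
            pathways.direct_scores(f, sensory, targets),
            pathways.indirect_scores(f, sensory, inter, targets, max_layers=2)],
            ignore_index=True)
        got = table.groupby(["source", "target"])["score"].sum()
        for key, truth_val in sim.truth["pathway_sums"].items():
            s, t = key.split("->")
            total = truth_val["direct"] + truth_val["indirect"]
            assert got.get((s, t), 0.0) == pytest.approx(total, abs=1e-12)

    def test_generated_files_parse_without_warnings(self, tmp_path, caplog):
        paths = generate_circuit(small_config(21)).write(tmp_path)
        with caplog.at_level("WARNING"):
            conn = circuit.read_connectors(paths["connectors"])
            ann = circuit.read_annotations(paths["annotations"])
            circuit.build_counts(conn, ann)
            for swc in sorted((tmp_path / "skeletons").iterdir()):
                read_swc(swc)
        assert caplog.text == ""

    def test_pair_totals_near_expectation(self):
        """Per-edge synapse totals stay within 4 SD of their expectation."""
        cfg_proto = small_config(0, peripheral_zone_rate=0.0)
        edge = cfg_proto.edges[0]  # S -> I
        n_pre = n_post = 6  # 3 per hemisphere, both hemispheres
        p_pairwise = edge.p_connect  # lateral factors average out over pairs
        exp_conn = n_pre * n_post * p_pairwise
        mean_pairs = edge.mean_pairs
        expected = exp_conn * mean_pairs
        # var per potential pair: Bernoulli(p) x shifted Poisson
        var_pair = p_pairwise * ((mean_pairs - 1) + mean_pairs ** 2) \
            - (p_pairwise * mean_pairs) ** 2
        sd = np.sqrt(n_pre * n_post * var_pair)
        totals = []
        for seed in range(20):
            sim = generate_circuit(small_config(seed,
                                                peripheral_zone_rate=0.0))
            tot = sum(n for key, n in sim.truth["counts"].items()
                      if key.startswith("S.") and "->I." in key)
            totals.append(tot)
        assert abs(np.mean(totals) - expected) < 4 * sd / np.sqrt(20)

    def test_invalid_configs_rejected_before_generation(self):
        with pytest.raises(ValueError, match="unique"):
            generate_circuit(CircuitConfig(
                seed=0, clusters=[ClusterSpec("X", "motor", 1),
                                  ClusterSpec("X", "motor", 1)], edges=[]))
        with pytest.raises(ValueError, match="asymmetry_eps"):
            generate_circuit(small_config(0, asymmetry_eps=2.0))
        cfg = small_config(0)
        cfg.edges[0].p_connect = 0.9  # effective probability above 1
        with pytest.raises(ValueError, match="exceeds 1"):
            generate_circuit(cfg)

    def test_demo_config_is_valid_and_layered(self):
        sim = generate_circuit(default_demo_config(2))
        classes = set(sim.annotations["cell_class"])
        assert {"sensory", "interneuron", "motor", "modulatory"} <= classes
        assert (sim.annotations["hemisphere"] == "unpaired").any()
        assert sim.truth["total_pairs"] > 0


class TestGenerateTrace:
    def test_noiseless_single_trigger_completion(self):
        cfg = TraceConfig(seed=0, duration_s=30.0, trigger_rate_per_min=4.0,
                          completion_prob=1.0, noise_sd=0.0)
        trace, truth = generate_trace(cfg)
        assert len(truth["trigger_times"]) >= 1
        t0 = truth["trigger_times"][0]
        assert truth["roi2_event_times"][0] == pytest.approx(
            t0 + cfg.latency_s)
        assert trace.roi1.max() > 0.9

    def test_no_completion_leaves_roi2_flat(self):
        cfg = TraceConfig(seed=1, duration_s=60.0, completion_prob=0.0,
                          noise_sd=0.0)
        _, truth = generate_trace(cfg)
        assert truth["roi2_event_times"] == []

    def test_determinism(self):
        a, ta = generate_trace(TraceConfig(seed=5))
        b, tb = generate_trace(TraceConfig(seed=5))
        assert np.array_equal(a.roi1, b.roi1)
        assert ta == tb

    def test_planted_events_recovered_with_high_fidelity(self):
        """Detector sensitivity and precision both >= 0.95 at 5% noise."""
        sens, prec = [], []
        for seed in range(10):
            trace, truth = generate_trace(TraceConfig(
                seed=seed, duration_s=300.0, noise_sd=0.05))
            det = detect_events(trace.t, trace.roi1, trace.sampling_rate)
            true_times = np.asarray(truth["trigger_times"])
            hits = sum(1 for tt in true_times
                       if len(det) and np.min(np.abs(det - tt)) < 0.5)
            sens.append(hits / len(true_times))
            fp = sum(1 for d in det if np.min(np.abs(true_times - d)) >= 0.5)
            prec.append((len(det) - fp) / len(det))
        assert np.mean(sens) >= 0.95
        assert np.mean(prec) >= 0.95

    def test_refractory_faster_than_rate_rejected(self):
        with pytest.raises(ValueError, match="refractory"):
            generate_trace(TraceConfig(seed=0, trigger_rate_per_min=40.0,
                                       refractory_s=2.0))

    def test_end_to_end_completion_flags_recovered(self):
        trace, truth = generate_trace(TraceConfig(
            seed=3, n_triggers=60, completion_prob=0.6, noise_sd=0.05))
        res = analyze_trace(trace)
        assert res["n_triggers"] == 60
        assert res["n_completed"] == sum(truth["completed_flags"])
        assert res["n_orphans"] == 0
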