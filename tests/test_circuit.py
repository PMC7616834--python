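"""Count/fraction matrices, cluster aggregation, budgets and tallies."""

import numpy as np
import pandas as pd
import pytest

from conftest import annotation_table, connector_table
from vagusconn import circuit

NEURONS = annotation_table([
    ("A", "sensory", "SA", "L", "mechano"),
    ("B", "interneuron", "IB", "L", None),
    ("C", "modulatory", "MC", "R", None),
    ("U", "sensory", "SU", "unpaired", "chemo"),
])


def pair_rows(pairs, region="CNS"):
    """pairs: list of (pre, post); one connector per pair."""
    return connector_table([
        (f"c{i}", pre, 1, post, 1, region, None)
        for i, (pre, post) in enumerate(pairs)])


class TestBuildCounts:
    def test_polyadic_connector_contributes_one_pair_per_partner(self):
        conn = connector_table([
            ("c1", "A", 1, "B", 2, "CNS", None),
            ("c1", "A", 1, "C", 3, "CNS", None)])
        m = circuit.build_counts(conn, NEURONS)
        assert m.loc["A", "B"] == 1 and m.loc["A", "C"] == 1
        assert m.to_numpy().sum() == 2

    def test_empty_table_gives_zero_matrix(self):
        m = circuit.build_counts(pair_rows([]), NEURONS)
        assert (m.to_numpy() == 0).all()
        assert list(m.index) == list(NEURONS["neuron_id"])

    def test_unknown_neurons_dropped_with_warning(self, caplog):
        conn = pair_rows([("A", "B"), ("A", "ghost")])
        with caplog.at_level("WARNING"):
            m = circuit.build_counts(conn, NEURONS)
        assert m.to_numpy().sum() == 1
        assert "ghost" in caplog.text

    def test_total_equals_pair_rows(self, rng):
        pre_post = [("A", "B"), ("A", "C"), ("B", "C"), ("U", "B")]
        pairs = [pre_post[i] for i in rng.integers(0, 4, size=60)]
        m = circuit.build_counts(pair_rows(pairs), NEURONS)
        assert m.to_numpy().sum() == 60


class TestInputFractions:
    def test_forced_by_column_totals(self):
        counts = pd.DataFrame({"t": [2, 3, 5]}, index=["a", "b", "c"])
        frac = circuit.input_fractions(counts)
        assert list(frac["t"]) == pytest.approx([0.2, 0.3, 0.5])

    def test_zero_input_column_is_undefined_not_zero(self):
        counts = pd.DataFrame({"t": [1, 1], "empty": [0, 0]}, index=["a", "b"])
        frac = circuit.input_fractions(counts)
        assert frac["empty"].isna().all()
        assert frac["t"].sum() == pytest.approx(1.0)

    def test_fractions_invert_to_counts(self, rng):
        counts = pd.DataFrame(rng.integers(0, 9, size=(6, 6)),
                              index=list("abcdef"), columns=list("abcdef"))
        frac = circuit.input_fractions(counts)
        totals = counts.sum(axis=0)
        recovered = frac.mul(totals, axis=1).fillna(0.0)
        assert np.allclose(recovered.to_numpy(),
                           counts.to_numpy().astype(float))

    def test_closed_circuit_columns_sum_to_one(self, rng):
        counts = pd.DataFrame(rng.integers(1, 5, size=(5, 5)),
                              index=list("abcde"), columns=list("abcde"))
        frac = circuit.input_fractions(counts)
        assert np.allclose(frac.sum(axis=0), 1.0, atol=1e-12)


class TestAggregateByCluster:
    def test_singleton_clusters_identity(self):
        m = circuit.build_counts(pair_rows([("A", "B"), ("A", "C")]), NEURONS)
        agg = circuit.aggregate_by_cluster(m, NEURONS)
        assert agg.loc["SA", "IB"] == 1 and agg.loc["SA", "MC"] == 1

    def test_outgoing_percent(self):
        neurons = annotation_table([
            ("x1", "sensory", "X", "L", "m"), ("x2", "sensory", "X", "R", "m"),
            ("y1", "motor", "Y", "L", None), ("z1", "motor", "Z", "L", None)])
        pairs = [("x1", "y1")] * 20 + [("x2", "z1")] * 30
        m = circuit.build_counts(pair_rows(pairs), neurons)
        pct = circuit.aggregate_by_cluster(m, neurons, percent_of_out=True)
        assert pct.loc["X", "Y"] == pytest.approx(40.0)
        assert pct.loc["X", "Z"] == pytest.approx(60.0)


class TestIoBalance:
    def test_hybrid_half_share(self):
        pairs = [("B", "A")] * 10 + [("A", "B")] * 10
        bal = circuit.io_balance("A", pair_rows(pairs))
        assert (bal.inputs, bal.outputs) == (10, 10)
        assert bal.input_share == pytest.approx(0.5)

    def test_pure_output_and_undefined(self):
        bal = circuit.io_balance("A", pair_rows([("A", "B")] * 5))
        assert bal.input_share == 0.0
        assert circuit.io_balance("C", pair_rows([])).input_share is None

    def test_region_filter(self):
        conn = pd.concat([pair_rows([("A", "B")] * 3, region="CNS"),
                          pair_rows([("A", "B")] * 7, region="periphery")],
                         ignore_index=True)
        assert circuit.io_balance("A", conn, region="CNS").outputs == 3
        assert circuit.io_balance("A", conn).outputs == 10


def mirrored_neurons():
    return annotation_table([
        ("s.L", "sensory", "S", "L", "m"), ("s.R", "sensory", "S", "R", "m"),
        ("t.L", "motor", "T", "L", None), ("t.R", "motor", "T", "R", None),
        ("u", "sensory", "SU", "unpaired", "m")])


class TestHemisphereBudgets:
    def test_mirrored_circuit_is_balanced(self):
        pairs = ([("s.L", "t.L")] * 4 + [("s.R", "t.R")] * 4 +
                 [("s.L", "t.R")] * 2 + [("s.R", "t.L")] * 2)
        b = circuit.hemisphere_budgets(pair_rows(pairs), mirrored_neurons(),
                                       "T", "in")
        assert b.LL == b.RR == 4 and b.LR == b.RL == 2
        assert b.total == 12

    def test_all_ipsilateral_left(self):
        b = circuit.hemisphere_budgets(pair_rows([("s.L", "t.L")] * 5),
                                       mirrored_neurons(), "T", "in")
        assert (b.LL, b.RR, b.LR, b.RL) == (5, 0, 0, 0)

    def test_unpaired_neurons_excluded_and_counted(self):
        pairs = [("s.L", "t.L")] * 3 + [("u", "t.L")] * 2
        b = circuit.hemisphere_budgets(pair_rows(pairs), mirrored_neurons(),
                                       "T", "in")
        assert b.LL == 3 and b.excluded_unpaired == 2

    def test_unknown_cluster_raises(self):
        with pytest.raises(KeyError):
            circuit.hemisphere_budgets(pair_rows([]), mirrored_neurons(),
                                       "nope", "in")

    def test_mirror_relabeling_swaps_budgets(self):
        pairs = ([("s.L", "t.L")] * 6 + [("s.R", "t.R")] * 2 +
                 [("s.L", "t.R")] * 3 + [("s.R", "t.L")] * 1)
        conn = pair_rows(pairs)
        b = circuit.hemisphere_budgets(conn, mirrored_neurons(), "T", "in")
        swap = {"s.L": "s.R", "s.R": "s.L", "t.L": "t.R", "t.R": "t.L"}
        mirrored = conn.assign(
            pre_neuron=conn["pre_neuron"].map(lambda x: swap.get(x, x)),
            post_neuron=conn["post_neuron"].map(lambda x: swap.get(x, x)))
        bm = circuit.hemisphere_budgets(mirrored, mirrored_neurons(), "T", "in")
        assert (bm.LL, bm.RR, bm.LR, bm.RL) == (b.RR, b.LL, b.RL, b.LR)


class TestPeripheralZones:
    def test_empty_and_planted_tallies(self):
        assert circuit.peripheral_zone_tally(pair_rows([])).empty
        conn = connector_table(
            [(f"z{i}", "C", 1, None, None, "periphery", "HCG")
             for i in range(3)] +
            [(f"z{i+3}", "C", 1, None, None, "periphery", "PVG")
             for i in range(2)])
        tally = circuit.peripheral_zone_tally(conn)
        got = tally.set_index("tissue_tag")["n"].to_dict()
        assert got == {"HCG": 3, "PVG": 2}
        assert tally["n"].sum() == 5

    def test_untagged_zone_is_validation_error(self):
        conn = connector_table([("z0", "C", 1, None, None, "periphery", None)])
        with pytest.raises(ValueError, match="tissue_tag"):
            circuit.peripheral_zone_tally(conn)


class TestValidation:
    def test_sensory_without_modality_rejected(self):
        bad = annotation_table([("A", "sensory", "SA", "L", None)])
        with pytest.raises(ValueError, match="modality"):
            circuit.validate_annotations(bad)

    def test_tsv_round_trip(self, tmp_path):
        conn = connector_table([
            ("c1", "A", 1, "B", 2, "CNS", None),
            ("z1", "C", 4, None, None, "periphery", "HCG")])
        circuit.write_connectors(conn, tmp_path / "c.tsv")
        back = circuit.read_connectors(tmp_path / "c.tsv")
        assert list(back["connector_id"]) == ["c1", "z1"]
        assert pd.isna(back.loc[1, "post_neuron"])
        circuit.write_annotations(NEURONS, tmp_path / "a.tsv")
        back_n = circuit.read_annotations(tmp_path / "a.tsv")
        assert back_n.equals(NEURONS)
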