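"""Port-pattern derivation, feedback-loop classes and graph abstractions."""

import fnmatch
import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from antlobe.motifs import (
    CellClass,
    ExtractionConfig,
    FeedbackLoopClass,
    NeuronRecord,
    ParseError,
    PortCounts,
    SynapseRecord,
    celltype_graph,
    classify_feedback_loop,
    classify_totals,
    count_port_synapses,
    derive_port_pattern,
    enumerate_port_patterns,
    filter_by_confidence,
    is_feedback_pattern,
    pattern_report,
    read_tables,
    select_al_lns,
)

CFG = ExtractionConfig()


class TestPatternEnumeration:
    def test_fifteen_unique_codes(self):
        patterns = enumerate_port_patterns()
        assert len(patterns) == 15
        assert len(set(patterns)) == 15
        assert "0000" not in patterns
        assert "1111" in patterns
        assert patterns == sorted(patterns)

    def test_eight_feedback_patterns_by_brute_force(self):
        # independent oracle: glob-match the three clauses over all 16 codes
        def oracle(code: str) -> bool:
            return any(
                fnmatch.fnmatch(code, pat) for pat in ("11??", "??11", "1??1")
            )

        all_codes = ["".join(b) for b in itertools.product("01", repeat=4)]
        assert sum(oracle(c) for c in all_codes) == 8
        for code in enumerate_port_patterns():
            assert is_feedback_pattern(code) == oracle(code)
        assert sum(is_feedback_pattern(c) for c in enumerate_port_patterns()) == 8

    @pytest.mark.parametrize(
        "code,expected", [("1100", True), ("0110", False), ("1001", True)]
    )
    def test_feedback_clauses(self, code, expected):
        assert is_feedback_pattern(code) is expected

    @pytest.mark.parametrize("bad", ["110", "11000", "11a0", "2100"])
    def test_malformed_codes_raise(self, bad):
        with pytest.raises(ValueError):
            is_feedback_pattern(bad)


class TestPatternDerivation:
    @pytest.mark.parametrize(
        "counts,expected",
        [
            ((10, 10, 10, 10), "1111"),
            ((1, 1, 1, 1), "0000"),  # total 4 below the glomerular threshold
            ((0, 8, 9, 7), "0111"),
            ((2, 2, 1, 1), "0000"),  # total passes, no digit does
            ((6, 0, 0, 0), "1000"),
            ((5, 5, 5, 5), "0000"),  # counts equal to the digit threshold fail it
            ((0, 0, 0, 6), "0001"),
        ],
    )
    def test_threshold_rules(self, counts, expected):
        assert derive_port_pattern(PortCounts(*counts), CFG) == expected

    @given(counts=st.tuples(*[st.integers(0, 20)] * 4))
    def test_matches_brute_force_oracle(self, counts):
        def oracle(c):
            if sum(c) < 5:
                return "0000"
            return "".join("1" if x > 5 else "0" for x in c)

        assert derive_port_pattern(PortCounts(*counts), CFG) == oracle(counts)


class TestConfidenceFilter:
    @pytest.mark.parametrize(
        "pre,post,kept",
        [
            (0.71, 0.90, True),
            (0.70, 0.90, False),  # strict: equal to the threshold is dropped
            (0.90, 0.50, False),  # both sites must pass
            (0.90, 0.70, False),
            (0.701, 0.701, True),
        ],
    )
    def test_boundaries(self, pre, post, kept):
        syn = [SynapseRecord("a", "b", pre, post, "DM4")]
        assert (len(filter_by_confidence(syn, CFG)) == 1) is kept


def _mini_population():
    neurons = [
        NeuronRecord("osn1", CellClass.OSN, receptor_type="Or59b"),
        NeuronRecord("osn2", CellClass.OSN, receptor_type="Or59b"),
        NeuronRecord("pn1", CellClass.PN, pn_subtype="uPN-adPN"),
        NeuronRecord("vpn1", CellClass.PN, pn_subtype="vPN"),
        NeuronRecord("ln1", CellClass.LN),
    ]
    return neurons


class TestPortCounting:
    def test_direct_count(self):
        neurons = _mini_population()
        syn = [SynapseRecord("ln1", "osn1", 0.9, 0.9, "DL5")] * 3
        counts = count_port_synapses("ln1", "DL5", syn, neurons)
        assert counts.as_tuple() == (3, 0, 0, 0)

    def test_other_glomerulus_not_counted(self):
        neurons = _mini_population()
        syn = [SynapseRecord("ln1", "osn1", 0.9, 0.9, "DM4")] * 3
        counts = count_port_synapses("ln1", "DL5", syn, neurons)
        assert counts.as_tuple() == (0, 0, 0, 0)

    def test_vpn_excluded_from_pn_ports(self):
        neurons = _mini_population()
        syn = [
            SynapseRecord("ln1", "vpn1", 0.9, 0.9, "DL5"),
            SynapseRecord("ln1", "pn1", 0.9, 0.9, "DL5"),
            SynapseRecord("vpn1", "ln1", 0.9, 0.9, "DL5"),
        ]
        counts = count_port_synapses("ln1", "DL5", syn, neurons)
        assert counts.ln_to_pn == 1
        assert counts.pn_to_ln == 0
        relaxed = count_port_synapses(
            "ln1", "DL5", syn, neurons, ExtractionConfig(exclude_vpn=False)
        )
        assert relaxed.ln_to_pn == 2
        assert relaxed.pn_to_ln == 1

    def test_non_ln_id_raises(self):
        neurons = _mini_population()
        with pytest.raises(ValueError):
            count_port_synapses("osn1", "DL5", [], neurons)


class TestLoopClassification:
    @pytest.mark.parametrize(
        "totals,expected",
        [
            ((12, 9, 1, 2), FeedbackLoopClass.OSN_LN_OSN),
            ((0, 0, 7, 11), FeedbackLoopClass.PN_LN_PN),
            ((0, 0, 0, 0), FeedbackLoopClass.NONE),
            ((10, 10, 10, 10), FeedbackLoopClass.MIXED),
            ((6, 6, 3, 3), FeedbackLoopClass.NONE),  # PN side sum 6 not < 5
            ((6, 6, 2, 2), FeedbackLoopClass.OSN_LN_OSN),
            ((5, 9, 0, 0), FeedbackLoopClass.NONE),  # 5 is not more than 5
        ],
    )
    def test_rules(self, totals, expected):
        assert classify_totals(*totals, cfg=CFG) is expected

    @given(totals=st.tuples(*[st.integers(0, 15)] * 4))
    def test_classes_mutually_exclusive(self, totals):
        """No totals tuple satisfies two class rules at once."""
        from_osn, to_osn, from_pn, to_pn = totals
        hits = [
            from_osn > 5 and to_osn > 5 and from_pn > 5 and to_pn > 5,
            from_osn > 5 and to_osn > 5 and (from_pn + to_pn) < 5,
            from_pn > 5 and to_pn > 5 and (from_osn + to_osn) < 5,
        ]
        assert sum(hits) <= 1
        cls = classify_totals(*totals, cfg=CFG)
        if hits[0]:
            assert cls is FeedbackLoopClass.MIXED
        elif hits[1]:
            assert cls is FeedbackLoopClass.OSN_LN_OSN
        elif hits[2]:
            assert cls is FeedbackLoopClass.PN_LN_PN
        else:
            assert cls is FeedbackLoopClass.NONE

    def test_scoped_classification(self):
        neurons = _mini_population()
        syn = (
            [SynapseRecord("osn1", "ln1", 0.9, 0.9, "DL5")] * 7
            + [SynapseRecord("ln1", "osn1", 0.9, 0.9, "DL5")] * 8
            + [SynapseRecord("pn1", "ln1", 0.9, 0.9, "DM4")] * 9
        )
        assert (
            classify_feedback_loop("ln1", "DL5", syn, neurons, CFG)
            is FeedbackLoopClass.OSN_LN_OSN
        )
        assert (
            classify_feedback_loop("ln1", "DM4", syn, neurons, CFG)
            is FeedbackLoopClass.NONE
        )


class TestLNInclusion:
    @pytest.mark.parametrize("n_syn,kept", [(11, True), (10, False), (0, False)])
    def test_boundary(self, n_syn, kept):
        neurons = _mini_population()
        syn = [SynapseRecord("osn1", "ln1", 0.9, 0.9, "DL5")] * n_syn
        assert (["ln1"] == select_al_lns(neurons, syn, CFG)) is kept


class TestReadTables:
    def _write(self, tmp_path, synapses: pd.DataFrame, neurons: pd.DataFrame):
        sp = tmp_path / "syn.csv"
        np_ = tmp_path / "neu.csv"
        synapses.to_csv(sp, index=False)
        neurons.to_csv(np_, index=False)
        return sp, np_

    def _tables(self):
        neurons = pd.DataFrame(
            [
                ("osn1", "OSN", "Or59b", "none", "DM4"),
                ("pn1", "PN", "", "uPN-adPN", "DM4"),
                ("ln1", "LN", "", "none", ""),
            ],
            columns=["neuron_id", "cell_class", "receptor_type", "pn_subtype", "glomeruli"],
        )
        synapses = pd.DataFrame(
            [
                ("osn1", "pn1", 0.95, 0.9, "DM4"),
                ("osn1", "ln1", 0.8, 0.85, "DM4"),
                ("ln1", "pn1", 0.99, 0.72, "DM4"),
            ],
            columns=["pre_id", "post_id", "pre_conf", "post_conf", "glomerulus"],
        )
        return synapses, neurons

    def test_well_formed_fixture(self, tmp_path):
        syn, neu = self._write(tmp_path, *self._tables())
        synapses, neurons = read_tables(syn, neu)
        assert len(synapses) == 3
        assert len(neurons) == 3
        assert synapses[0].pre_confidence == 0.95

    def test_dangling_id_names_row_and_id(self, tmp_path):
        from antlobe.synth import corrupt_fixture

        synapses, neurons = corrupt_fixture(self._tables(), "dangling_id")
        syn, neu = self._write(tmp_path, synapses, neurons)
        with pytest.raises(ParseError, match="row 4.*GHOST"):
            read_tables(syn, neu)

    def test_bad_confidence_rejected(self, tmp_path):
        from antlobe.synth import corrupt_fixture

        synapses, neurons = corrupt_fixture(self._tables(), "bad_confidence")
        syn, neu = self._write(tmp_path, synapses, neurons)
        with pytest.raises(ParseError, match="confidence"):
            read_tables(syn, neu)

    def test_missing_column_rejected(self, tmp_path):
        from antlobe.synth import corrupt_fixture

        synapses, neurons = corrupt_fixture(self._tables(), "missing_column")
        syn, neu = self._write(tmp_path, synapses, neurons)
        with pytest.raises(ParseError, match="post_conf"):
            read_tables(syn, neu)

    def test_bad_cell_class_rejected(self, tmp_path):
        synapses, neurons = self._tables()
        neurons.loc[0, "cell_class"] = "KC"
        syn, neu = self._write(tmp_path, synapses, neurons)
        with pytest.raises(ParseError, match="cell_class"):
            read_tables(syn, neu)


class TestCellTypeGraph:
    def _population(self):
        neurons = [
            NeuronRecord("a1", CellClass.OSN, receptor_type="OrA"),
            NeuronRecord("a2", CellClass.OSN, receptor_type="OrA"),
            NeuronRecord("b1", CellClass.PN, pn_subtype="uPN-adPN",
                         glomeruli=frozenset({"DM4"})),
        ]
        synapses = [SynapseRecord("a1", "b1", 0.9, 0.9, "DM4")] * 2 + [
            SynapseRecord("a2", "b1", 0.9, 0.9, "DM4")
        ]
        return neurons, synapses

    def test_celltype_edge_weight_totals(self):
        neurons, synapses = self._population()
        g = celltype_graph(neurons, synapses, "cell_type", 0)
        assert g.number_of_edges() == 1
        (u, v, data), = g.edges(data=True)
        assert data["weight"] == 3

    def test_min_synapse_filter_drops_edge(self):
        neurons, synapses = self._population()
        g = celltype_graph(neurons, synapses, "cell_type", 5)
        assert g.number_of_edges() == 0

    def test_within_type_self_loop(self):
        neurons, _ = self._population()
        synapses = [SynapseRecord("a1", "a2", 0.9, 0.9, "DM4")]
        g = celltype_graph(neurons, synapses, "cell_type", 0)
        assert g.has_edge("OSN:OrA", "OSN:OrA")

    def test_neuron_level_collapses_to_celltype_level(self, planted_small_records):
        """Grouping the neuron graph by type reproduces the cell-type graph."""
        synapses, neurons = planted_small_records
        from antlobe.motifs import _default_type_key, _index_neurons

        idx = _index_neurons(neurons)
        g_neuron = celltype_graph(neurons, synapses, "neuron", 0)
        g_type = celltype_graph(neurons, synapses, "cell_type", 0)
        collapsed: dict[tuple[str, str], int] = {}
        for u, v, data in g_neuron.edges(data=True):
            pair = (_default_type_key(idx[u]), _default_type_key(idx[v]))
            collapsed[pair] = collapsed.get(pair, 0) + data["weight"]
        expected = {
            (u, v): data["weight"] for u, v, data in g_type.edges(data=True)
        }
        assert collapsed == expected

    def test_invalid_arguments(self):
        neurons, synapses = self._population()
        with pytest.raises(ValueError):
            celltype_graph(neurons, synapses, "lineage", 0)
        with pytest.raises(ValueError):
            celltype_graph(neurons, synapses, "neuron", -1)


class TestPatternReport:
    def test_recovers_planted_patterns(self, planted_small, planted_small_records):
        synapses, neurons = planted_small_records
        report = pattern_report(synapses, neurons)
        merged = report.merge(
            planted_small.truth, on=["ln_id", "glomerulus"], how="right",
            suffixes=("_found", "_planted"),
        )
        assert len(merged) == len(planted_small.truth)
        assert (merged["pattern_found"] == merged["pattern_planted"]).all()
        assert (merged["loop_class_found"] == merged["loop_class_planted"]).all()

    def test_feedback_flag_consistent_with_pattern(self, planted_small_records):
        synapses, neurons = planted_small_records
        report = pattern_report(synapses, neurons)
        nonzero = report[report["pattern"] != "0000"]
        expected = nonzero["pattern"].map(is_feedback_pattern)
        assert (nonzero["feedback"] == expected).all()
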