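"""Circuit composition: glomeruli, motif attachment, crossbars, ablation."""

import numpy as np
import pytest

from antlobe.composer import (
    CircuitEdge,
    CircuitModel,
    FeedbackMotif,
    ablate,
    add_ln3,
    attach_motif,
    audit_port_licensing,
    build_crossbar,
    build_glomerulus,
    interconnect_pair,
    restore,
)
from antlobe.synth import make_pair_fixture


def _glom(name="DM4", n_osn=4, n_pn=2, fill=10):
    return build_glomerulus(name, n_osn, n_pn, np.full((n_osn, n_pn), fill))


def _port_connections(circuit):
    """Distinct (motif, glomerulus, digit) triples realized by port edges."""
    triples = set()
    for e in circuit.edges:
        if e.kind != "port":
            continue
        pre_c = circuit.neurons[e.pre].cell_class
        post_c = circuit.neurons[e.post].cell_class
        digit = {("LN", "OSN"): 0, ("OSN", "LN"): 1, ("LN", "PN"): 2, ("PN", "LN"): 3}[
            (pre_c, post_c)
        ]
        triples.add((e.motif_id, e.glomerulus, digit))
    return triples


class TestGlomerulus:
    def test_single_pn_glomerulus_is_valid(self):
        g = build_glomerulus("DL5", 15, 1, np.full((15, 1), 40))
        assert g.n_pn == 1
        assert len(g.pn_ids) == 1

    def test_zero_osns_rejected(self):
        with pytest.raises(ValueError):
            build_glomerulus("DM4", 0, 1, np.zeros((0, 1), dtype=int))

    def test_all_zero_feedforward_warns(self):
        with pytest.warns(UserWarning, match="all-zero feedforward"):
            build_glomerulus("DM4", 2, 1, np.zeros((2, 1), dtype=int))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            build_glomerulus("DM4", 3, 2, np.full((2, 3), 5))

    def test_feedforward_edges_follow_count_matrix(self):
        ff = np.array([[3, 0], [0, 7]])
        circuit = CircuitModel()
        circuit.add_glomerulus(build_glomerulus("DM4", 2, 2, ff))
        ff_edges = {(e.pre, e.post): e.count for e in circuit.edges}
        assert ff_edges == {("DM4/OSN0", "DM4/PN0"): 3, ("DM4/OSN1", "DM4/PN1"): 7}


class TestAttachMotif:
    def test_ln1_touches_only_osn_ports(self):
        circuit = CircuitModel()
        circuit.add_glomerulus(_glom())
        attach_motif(circuit, FeedbackMotif("LN1"), ["DM4"])
        digits = {d for _, _, d in _port_connections(circuit)}
        assert digits == {0, 1}
        assert all(
            circuit.neurons[e.post].cell_class != "PN"
            for e in circuit.edges
            if e.kind == "port"
        )

    def test_ln1_feedback_is_presynaptic(self):
        circuit = CircuitModel()
        circuit.add_glomerulus(_glom())
        attach_motif(circuit, FeedbackMotif("LN1"), ["DM4"])
        to_osn = [
            e for e in circuit.edges if circuit.neurons[e.post].cell_class == "OSN"
            and e.kind == "port"
        ]
        assert to_osn
        assert all(e.presynaptic for e in to_osn)

    def test_shared_ln2_spans_both_glomeruli(self):
        circuit = CircuitModel()
        circuit.add_glomerulus(_glom("DM4"))
        circuit.add_glomerulus(_glom("DL5", n_pn=1))
        mid = attach_motif(circuit, FeedbackMotif("LN2"), ["DM4", "DL5"])
        conns = _port_connections(circuit)
        assert (mid, "DM4", 2) in conns and (mid, "DM4", 3) in conns
        assert (mid, "DL5", 2) in conns and (mid, "DL5", 3) in conns
        assert {d for _, _, d in conns} == {2, 3}
        assert len(circuit.motif_neurons(mid)) == 1  # one LN spanning both

    def test_zero_pattern_warns_and_adds_no_edges(self):
        circuit = CircuitModel()
        circuit.add_glomerulus(_glom())
        n_before = len(circuit.edges)
        with pytest.warns(UserWarning, match="0000"):
            attach_motif(
                circuit, FeedbackMotif("custom", {"DM4": "0000"}), ["DM4"]
            )
        assert len(circuit.edges) == n_before

    def test_ln3_cannot_attach_to_ports(self):
        circuit = CircuitModel()
        circuit.add_glomerulus(_glom())
        with pytest.raises(ValueError, match="add_ln3"):
            attach_motif(circuit, FeedbackMotif("LN3"), ["DM4"])

    def test_unknown_glomerulus_rejected(self):
        circuit = CircuitModel()
        circuit.add_glomerulus(_glom())
        with pytest.raises(KeyError):
            attach_motif(circuit, FeedbackMotif("LN1"), ["VA1"])

    def test_motif_pattern_constraints(self):
        with pytest.raises(ValueError):
            FeedbackMotif("LN1", {"DM4": "0011"})
        with pytest.raises(ValueError):
            FeedbackMotif("LN2", {"DM4": "1100"})
        with pytest.raises(ValueError):
            FeedbackMotif("LN3", {"DM4": "1100"})

    def test_order_independence(self):
        def build(order):
            circuit = CircuitModel()
            circuit.add_glomerulus(_glom())
            for kind, mid in order:
                attach_motif(circuit, FeedbackMotif(kind), ["DM4"], motif_id=mid)
            return circuit

        a = build([("LN1", "m1"), ("LN2", "m2")])
        b = build([("LN2", "m2"), ("LN1", "m1")])
        assert sorted(map(repr, a.edges)) == sorted(map(repr, b.edges))


class TestLN3:
    def _with_two_motifs(self):
        circuit = CircuitModel()
        circuit.add_glomerulus(_glom())
        m1 = attach_motif(circuit, FeedbackMotif("LN1"), ["DM4"])
        m2 = attach_motif(circuit, FeedbackMotif("LN2"), ["DM4"])
        return circuit, m1, m2

    def test_bidirectional_edges_and_signs(self):
        circuit, m1, m2 = self._with_two_motifs()
        mid = add_ln3(circuit, [m1, m2])
        ln3_edges = [e for e in circuit.edges if e.kind == "ln"]
        assert len(ln3_edges) == 4  # 2 targets x both directions
        (ln3_id,) = circuit.motif_neurons(mid)
        for e in ln3_edges:
            if e.post == ln3_id:
                assert e.sign == "excitatory"
            else:
                assert e.pre == ln3_id and e.sign == "inhibitory"

    def test_empty_targets_rejected(self):
        circuit, *_ = self._with_two_motifs()
        with pytest.raises(ValueError):
            add_ln3(circuit, [])

    def test_ln3_target_rejected(self):
        circuit, m1, m2 = self._with_two_motifs()
        mid = add_ln3(circuit, [m1])
        with pytest.raises(ValueError):
            add_ln3(circuit, [mid])


class TestInterconnectPair:
    def test_default_five_motifs(self, pair_circuit):
        lns = [n for n in pair_circuit.neurons.values() if n.cell_class == "LN"]
        assert len(lns) == 5
        kinds = sorted(pair_circuit.motifs[n.motif_id].kind for n in lns)
        assert kinds == ["LN1", "LN1", "LN2", "LN2", "LN3"]

    def test_without_ln3_no_cross_glomerular_path(self):
        from antlobe.composer import PairMotifSpec

        glom_a, glom_b, _ = make_pair_fixture()
        circuit = interconnect_pair(glom_a, glom_b, PairMotifSpec(with_ln3=False))
        lns = [n for n in circuit.neurons.values() if n.cell_class == "LN"]
        assert len(lns) == 4
        # no LN touches both glomeruli and there are no LN-LN edges
        assert not [e for e in circuit.edges if e.kind == "ln"]
        for ln in lns:
            gloms = {
                e.glomerulus
                for e in circuit.edges
                if ln.neuron_id in (e.pre, e.post)
            }
            assert len(gloms) == 1

    def test_shared_ln2_style(self):
        from antlobe.composer import PairMotifSpec

        glom_a, glom_b, _ = make_pair_fixture()
        circuit = interconnect_pair(
            glom_a, glom_b,
            PairMotifSpec(ln2_per_glomerulus=False, shared_ln2=True, with_ln3=False),
        )
        ln2_ids = [
            mid for mid, m in circuit.motifs.items() if m.kind == "LN2"
        ]
        assert len(ln2_ids) == 1
        gloms = {
            e.glomerulus for e in circuit.edges if e.motif_id == ln2_ids[0]
        }
        assert gloms == {"DM4", "DL5"}

    def test_duplicate_names_rejected(self):
        with pytest.raises(ValueError):
            interconnect_pair(_glom("DM4"), _glom("DM4"))


class TestCrossbar:
    def test_two_by_two_all_ones(self):
        gloms = [_glom("DM4"), _glom("DL5", n_pn=1)]
        circuit = build_crossbar(
            gloms, {"LNa": {"DM4": "1111", "DL5": "1111"},
                    "LNb": {"DM4": "1111", "DL5": "1111"}}
        )
        assert len(_port_connections(circuit)) == 16  # 2 LNs x 2 glomeruli x 4 ports
        assert audit_port_licensing(circuit) == []

    def test_unknown_glomerulus_rejected(self):
        with pytest.raises(ValueError, match="unknown glomeruli"):
            build_crossbar([_glom("DM4")], {"LNa": {"VA1": "1111"}})

    def test_all_zero_matrix_warns(self):
        with pytest.warns(UserWarning, match="no edges"):
            circuit = build_crossbar([_glom("DM4")], {"LNa": {"DM4": "0000"}})
        assert _port_connections(circuit) == set()

    def test_round_trip_through_synapse_tables(self, tmp_path):
        """Extracting patterns from a serialized circuit reproduces the matrix."""
        from antlobe.motifs import pattern_report, read_tables

        matrix = {
            "LNa": {"DM4": "1100", "DL5": "0011"},
            "LNb": {"DM4": "1011"},
            "LNc": {"DL5": "1111"},
        }
        gloms = [_glom("DM4"), _glom("DL5", n_pn=1)]
        circuit = build_crossbar(gloms, matrix)
        syn_df, neu_df = circuit.to_synapse_tables()
        sp, np_ = tmp_path / "s.csv", tmp_path / "n.csv"
        syn_df.to_csv(sp, index=False)
        neu_df.to_csv(np_, index=False)
        synapses, neurons = read_tables(sp, np_)
        report = pattern_report(synapses, neurons)
        found = {
            (row.ln_id.split(":")[1].split("/")[0], row.glomerulus): row.pattern
            for row in report.itertuples()
        }
        expected = {
            (ln, g): p for ln, row in matrix.items() for g, p in row.items()
        }
        assert found == expected


class TestAblation:
    def _circuit(self):
        circuit = CircuitModel()
        circuit.add_glomerulus(_glom())
        m1 = attach_motif(circuit, FeedbackMotif("LN1"), ["DM4"], motif_id="m1")
        m2 = attach_motif(circuit, FeedbackMotif("LN2"), ["DM4"], motif_id="m2")
        return circuit, m1, m2

    def test_ablation_equals_building_without(self):
        circuit, _, m2 = self._circuit()
        ablate(circuit, m2)
        reference = CircuitModel()
        reference.add_glomerulus(_glom())
        attach_motif(reference, FeedbackMotif("LN1"), ["DM4"], motif_id="m1")
        assert sorted(map(repr, circuit.edges)) == sorted(map(repr, reference.edges))

    def test_idempotent(self):
        circuit, _, m2 = self._circuit()
        ablate(circuit, m2)
        edges_once = list(circuit.edges)
        ablate(circuit, m2)
        assert circuit.edges == edges_once

    def test_restore_recovers_original_edges(self):
        circuit, _, m2 = self._circuit()
        before = sorted(map(repr, circuit.edges))
        ablate(circuit, m2)
        restore(circuit, m2)
        assert sorted(map(repr, circuit.edges)) == before

    def test_unknown_motif_rejected(self):
        circuit, *_ = self._circuit()
        with pytest.raises(KeyError):
            ablate(circuit, "nope")


class TestAuditAndSerialization:
    def test_composed_circuits_pass_audit(self, pair_circuit):
        assert audit_port_licensing(pair_circuit) == []

    def test_unlicensed_edge_detected(self):
        circuit = CircuitModel()
        circuit.add_glomerulus(_glom())
        mid = attach_motif(circuit, FeedbackMotif("LN1"), ["DM4"])
        (ln_id,) = circuit.motif_neurons(mid)
        # LN1's pattern licenses no PN-side connection
        circuit.edges.append(
            CircuitEdge(ln_id, "DM4/PN0", 5, glomerulus="DM4", motif_id=mid)
        )
        violations = audit_port_licensing(circuit)
        assert len(violations) == 1
        assert "digit 2" in violations[0]

    def test_json_round_trip(self, pair_circuit, tmp_path):
        path = tmp_path / "circuit.json"
        pair_circuit.to_json(path)
        loaded = CircuitModel.from_json(path)
        assert sorted(loaded.neurons) == sorted(pair_circuit.neurons)
        assert sorted(map(repr, loaded.edges)) == sorted(map(repr, pair_circuit.edges))
        assert sorted(loaded.motifs) == sorted(pair_circuit.motifs)

    def test_graph_export(self, pair_circuit):
        g = pair_circuit.to_graph()
        assert g.number_of_nodes() == len(pair_circuit.neurons)
        assert all("weight" in d for _, _, d in g.edges(data=True))
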