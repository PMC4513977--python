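import random

import networkx as nx
import pytest

from sigmapnet import (
    GeneratorSpec,
    Interactome,
    candidate_interactors,
    compactness_metrics,
    evaluate_candidate,
    filter_binary_physical,
    generate_interactome,
    generate_map,
    module_expansion,
    pathexpand_select,
    protein_projection,
    read_psi_mitab,
)
from sigmapnet.ppi import DEFAULT_METHOD_WHITELIST, InteractionRecord, MitabFormatError
from sigmapnet.decompose import decompose
from sigmapnet.graph import build_reaction_graph

import _oracles as oracle


def mitab_line(a, b, method="MI:0018", name="two hybrid"):
    cols = [
        f"uniprotkb:{a}", f"uniprotkb:{b}", "-", "-", "-", "-",
        f'psi-mi:"{method}"({name})', "-", "pubmed:123", "taxid:9606",
        "taxid:9606", 'psi-mi:"MI:0407"(direct)', 'psi-mi:"MI:0469"(intact)',
        "intact:EBI-1", "-",
    ]
    return "\t".join(cols)


@pytest.fixture
def toy_mitab(tmp_path):
    lines = [
        mitab_line("AKT1", "SRC"),
        mitab_line("SRC", "AKT1"),  # duplicate pair from a second database
        mitab_line("PAK1", "PAK1"),  # self interaction, dropped later
        mitab_line("HRAS", "RAF1", method="MI:0004", name="affinity chromatography"),
        mitab_line("GRB2", "SOS1", method="MI:0090", name="complementation"),
    ]
    path = tmp_path / "toy.mitab"
    path.write_text("#header\n" + "\n".join(lines) + "\n")
    return path


class TestMitabReader:
    def test_toy_file_record_count(self, toy_mitab):
        records, report = read_psi_mitab(toy_mitab)
        assert len(records) == 5 and report.n_records == 5
        assert not report.skipped

    def test_wrong_column_count_names_line(self, tmp_path):
        bad = tmp_path / "bad.mitab"
        bad.write_text("a\tb\tc\n")
        with pytest.raises(MitabFormatError, match="line 1"):
            read_psi_mitab(bad)

    def test_alias_table_resolution_and_skip_report(self, tmp_path):
        path = tmp_path / "al.mitab"
        path.write_text(mitab_line("P31749", "Q9UQ66") + "\n" + mitab_line("P31749", "NOPE") + "\n")
        records, report = read_psi_mitab(path, aliases={"P31749": "AKT1", "Q9UQ66": "SRC"})
        assert [(r.a, r.b) for r in records] == [("AKT1", "SRC")]
        assert len(report.skipped) == 1

    def test_duplicate_pair_collapses_in_interactome(self, toy_mitab):
        records, _ = read_psi_mitab(toy_mitab)
        net = filter_binary_physical(records)
        assert frozenset({"AKT1", "SRC"}) in net.interactions
        assert len([i for i in net.interactions if i == frozenset({"AKT1", "SRC"})]) == 1


class TestBinaryPhysicalFilter:
    def test_whitelisted_kept_others_dropped(self, toy_mitab):
        records, _ = read_psi_mitab(toy_mitab)
        net = filter_binary_physical(records)
        assert net.interactions == {
            frozenset({"AKT1", "SRC"}),
            frozenset({"GRB2", "SOS1"}),
        }

    def test_self_interactions_dropped(self):
        rec = InteractionRecord("A", "A", frozenset({"MI:0018"}))
        assert filter_binary_physical([rec]).interactions == set()

    def test_ontology_ancestor_whitelisting(self):
        rec = InteractionRecord("A", "B", frozenset({"MI:9999"}))
        net = filter_binary_physical([rec], ontology_parents={"MI:9999": "MI:0018"})
        assert net.interactions == {frozenset({"A", "B"})}

    def test_empty_whitelist_rejected(self):
        with pytest.raises(ValueError):
            filter_binary_physical([], method_whitelist=set())

    def test_mixed_fixture_hand_count(self, tmp_path):
        # 10 records, 6 distinct whitelisted pairs by hand count
        lines = [
            mitab_line("A", "B"), mitab_line("A", "B"),
            mitab_line("A", "C"), mitab_line("B", "C", method="MI:0090", name="pca"),
            mitab_line("C", "D"), mitab_line("D", "E"),
            mitab_line("E", "F"),
            mitab_line("F", "G", method="MI:0114", name="xray"),
            mitab_line("G", "H", method="MI:0004", name="affinity"),
            mitab_line("H", "H"),
        ]
        p = tmp_path / "mixed.mitab"
        p.write_text("\n".join(lines) + "\n")
        records, _ = read_psi_mitab(p)
        assert len(filter_binary_physical(records).interactions) == 6


class TestCandidates:
    def test_disjoint_interactome_empty(self):
        net = Interactome()
        net.graph.add_edge("X", "Y")
        cands, coverage = candidate_interactors(net, {"AKT1"})
        assert cands == set() and coverage == 0

    def test_outside_protein_with_three_map_partners(self):
        net = Interactome()
        for p in ("AKT1", "SRC", "PAK1"):
            net.graph.add_edge("NEW", p)
        cands, coverage = candidate_interactors(net, {"AKT1", "SRC", "PAK1"})
        assert "NEW" in cands and coverage == 3


class TestCompactnessMetrics:
    def test_triangle_closed_form(self):
        md, mb, mc, pl = compactness_metrics(nx.complete_graph(3))
        assert (md, mc, pl) == (2.0, 1.0, 1.0) and mb == 0.0

    def test_path_of_three_closed_form(self):
        md, mb, mc, pl = compactness_metrics(nx.path_graph(3))
        assert mc == 0.0 and pl == pytest.approx(4 / 3)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_on_random_graphs(self, seed):
        g = nx.gnp_random_graph(14, 0.25, seed=seed)
        md, mb, mc, pl = compactness_metrics(g)
        n = g.number_of_nodes()
        assert md == pytest.approx(sum(oracle.degrees(g.nodes, g.edges).values()) / n)
        assert mb == pytest.approx(sum(oracle.betweenness(g.nodes, g.edges).values()) / n)
        assert mc == pytest.approx(sum(oracle.clustering(g.nodes, g.edges).values()) / n)
        assert pl == pytest.approx(oracle.characteristic_path_length(g.nodes, g.edges))


class TestEvaluateCandidate:
    def _net(self, edges):
        net = Interactome()
        net.graph.add_edges_from(edges)
        return net

    def test_pendant_vertex_rejected_by_path_length(self):
        base = nx.cycle_graph(4)
        net = self._net([("cand", 0)])
        rep = evaluate_candidate(base, net, "cand")
        assert rep.delta_path_length > 0 and not rep.accepted

    def test_apex_over_cycle_improves_clustering_and_paths(self):
        base = nx.cycle_graph(4)
        net = self._net([("cand", i) for i in range(4)])
        rep = evaluate_candidate(base, net, "cand")
        assert rep.delta_clustering > 0 and rep.delta_path_length < 0

    def test_no_partner_is_precondition_violation(self):
        base = nx.path_graph(3)
        with pytest.raises(ValueError):
            evaluate_candidate(base, self._net([("cand", "zzz")]), "cand")

    def test_verdict_independent_of_other_candidates(self):
        base = nx.cycle_graph(5)
        net = self._net([("a", i) for i in range(5)] + [("b", 0)])
        before = evaluate_candidate(base, net, "b")
        # evaluating (and notionally accepting) 'a' must not change 'b'
        evaluate_candidate(base, net, "a")
        after = evaluate_candidate(base, net, "b")
        assert before == after

    def test_k_of_4_relaxation(self):
        # triangle-closing candidate on a 3-path: degree and clustering
        # improve, betweenness and path length do not
        base = nx.path_graph(3)
        net = self._net([("cand", 0), ("cand", 1)])
        strict = evaluate_candidate(base, net, "cand", criteria="all")
        relaxed = evaluate_candidate(base, net, "cand", criteria="2-of-4")
        assert not strict.accepted and relaxed.accepted


@pytest.fixture(scope="module")
def bench(tmp_path_factory):
    spec = GeneratorSpec(seed=3)
    model, truth = generate_map(spec)
    path = tmp_path_factory.mktemp("ppi") / "bench.mitab"
    _, ppi_truth = generate_interactome(model, spec, path)
    records, report = read_psi_mitab(path)
    assert not report.skipped
    interactome = filter_binary_physical(records)
    return model, truth, ppi_truth, interactome


class TestBenchmarkSelection:
    def test_planted_candidates_accepted(self, bench):
        from sigmapnet import base_expansion_network, unique_protein_set

        model, _, ppi_truth, interactome = bench
        base = base_expansion_network(model, interactome)
        accepted, novel = pathexpand_select(
            base, interactome, set(unique_protein_set(model))
        )
        names = {r.candidate for r in accepted}
        assert set(ppi_truth.planted) <= names
        assert all(not r.in_original_map for r in novel)
        # deterministic ordering by (partners desc, symbol)
        keys = [(-r.n_map_partners, r.candidate) for r in accepted]
        assert keys == sorted(keys)

    def test_offmethod_records_filtered(self, bench):
        _, _, ppi_truth, interactome = bench
        kept = sum(len(interactome.partners(d)) for d in ppi_truth.decoys)
        total = sum(len(ppi_truth.partners[d]) for d in ppi_truth.decoys)
        assert kept < total  # the off-whitelist decoy records are gone

    def test_bridge_interactor_is_multi_module(self):
        spec = GeneratorSpec(
            n_modules=2, molecules_per_module=(4, 4), tf_layer_size=0,
            n_planted_candidates=0, n_decoys=0, seed=9,
        )
        model, truth = generate_map(spec)
        g = build_reaction_graph(model)
        modules, _, _ = decompose(g, model)
        net = Interactome()
        # bridge touches the two hubs; singleton touches one member pair
        net.graph.add_edges_from([("BRIDGE", "M0HUB"), ("BRIDGE", "M1HUB"),
                                  ("BRIDGE", "M0P1"), ("BRIDGE", "M0P2"),
                                  ("SOLO", "M1P1"), ("SOLO", "M1P2")])
        for m in modules:
            exp = module_expansion(m, net, modules, model, criteria="1-of-4")
            for cand, touched in exp.modules_touched.items():
                if cand == "BRIDGE":
                    assert len(touched) == 2 and cand in exp.multi_module
                if cand == "SOLO":
                    assert len(touched) == 1 and cand in exp.single_module
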