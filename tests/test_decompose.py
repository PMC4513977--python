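import random

import networkx as nx
import pytest

from sigmapnet import (
    MapModel,
    MapReaction,
    ModifierSign,
    ReactionClass,
    build_reaction_graph,
    completeness_check,
    decompose,
    generate_map,
    material_components,
    merge_overlapping,
    modular_projection,
    prune_tf_downstream,
    split_to_unique_cycle,
    strongly_connected_core,
)
from sigmapnet.decompose import Module, SubNetwork, jaccard, overlap_coefficient

import _oracles as oracle
from conftest import make_species


def digraph(nodes, edges):
    g = nx.DiGraph()
    for n, kind in nodes:
        g.add_node(n, kind=kind, label=n)
    for u, v in edges:
        g.add_edge(u, v, roles=frozenset({"REACTANT"}), sign="NONE")
    return g


S, R = "SPECIES", "REACTION"


class TestCore:
    def test_cycle_with_tail(self):
        g = digraph(
            [("A", S), ("R1", R), ("B", S), ("R2", R), ("R3", R), ("C", S)],
            [("A", "R1"), ("R1", "B"), ("B", "R2"), ("R2", "A"), ("B", "R3"), ("R3", "C")],
        )
        core, up, down, detached = strongly_connected_core(g)
        assert core.nodes == {"A", "R1", "B", "R2"}
        assert down == {"R3", "C"}
        assert up == set() and detached == set()

    def test_dag_has_empty_core(self):
        g = digraph([("A", S), ("R1", R), ("B", S)], [("A", "R1"), ("R1", "B")])
        core, _, _, detached = strongly_connected_core(g)
        assert core.nodes == frozenset()
        assert detached == {"A", "R1", "B"}

    @pytest.mark.parametrize("seed", range(30))
    def test_matches_mutual_reachability_oracle(self, seed):
        rng = random.Random(seed)
        g = nx.DiGraph()
        g.add_nodes_from((f"n{i}", {"kind": S}) for i in range(15))
        for i in range(15):
            for j in range(15):
                if i != j and rng.random() < 0.15:
                    g.add_edge(f"n{i}", f"n{j}")
        comps = [c for c in oracle.scc_by_reachability(g.nodes, g.edges) if len(c) > 1]
        core, _, _, _ = strongly_connected_core(g)
        if not comps:
            assert core.nodes == frozenset()
        else:
            expected = max(comps, key=lambda c: (len(c), tuple(sorted(c))))
            assert core.nodes == expected


class TestMaterialComponents:
    def _model_and_graph(self, species, reactions):
        model = MapModel(species=species, reactions=reactions)
        return model, build_reaction_graph(model)

    def test_one_molecule_three_states(self):
        species = [make_species(f"s{i}", name="RAF1") for i in range(3)]
        reactions = [
            MapReaction("r0", reactants=("s0",), products=("s1",)),
            MapReaction("r1", reactants=("s1",), products=("s2",)),
        ]
        model, g = self._model_and_graph(species, reactions)
        core = SubNetwork("core", frozenset(g.nodes))
        comps = material_components(core, model, g)
        assert len(comps) == 1 and len(comps[0].nodes) == 5

    def test_two_molecules_share_bridging_reaction(self):
        species = [make_species("a", name="HRAS"), make_species("b", name="RAF1")]
        reactions = [MapReaction("r", reactants=("a",), products=("b",))]
        model, g = self._model_and_graph(species, reactions)
        comps = material_components(SubNetwork("core", frozenset(g.nodes)), model, g)
        assert len(comps) == 2
        assert all("r" in c.nodes for c in comps)

    def test_generator_core_has_one_component_per_molecule(self, small_world):
        model, truth = small_world
        g = prune_tf_downstream(build_reaction_graph(model), set(truth.tf_ids))
        core, _, _, _ = strongly_connected_core(g)
        comps = material_components(core, model, g)
        n_molecules = sum(len(m) for m in truth.module_molecules.values())
        assert len(comps) == n_molecules


class TestMerge:
    def test_identical_subnets_collapse(self):
        a = SubNetwork("a", frozenset("xyz"))
        b = SubNetwork("b", frozenset("xyz"))
        assert len(merge_overlapping([a, b])) == 1

    def test_forced_merge_by_overlap_definition(self):
        a = SubNetwork("a", frozenset("ABCD"))
        b = SubNetwork("b", frozenset("CDE"))
        merged = merge_overlapping([a, b])  # overlap 2/3 >= 0.5
        assert len(merged) == 1 and merged[0].nodes == frozenset("ABCDE")

    def test_disjoint_unchanged(self):
        subnets = [SubNetwork("a", frozenset("AB")), SubNetwork("b", frozenset("CD"))]
        assert sorted(s.nodes for s in merge_overlapping(subnets)) == [
            frozenset("AB"),
            frozenset("CD"),
        ]

    def test_result_is_fixed_point_and_order_independent(self):
        rng = random.Random(3)
        subnets = [
            SubNetwork(f"s{i}", frozenset(rng.sample(range(12), rng.randint(2, 6))))
            for i in range(8)
        ]
        merged = merge_overlapping(subnets)
        assert merge_overlapping(merged) == merged
        for perm_seed in range(5):
            shuffled = subnets[:]
            random.Random(perm_seed).shuffle(shuffled)
            shuffled_nodes = sorted(
                (s.nodes for s in merge_overlapping(shuffled)), key=sorted
            )
            assert shuffled_nodes == sorted((s.nodes for s in merged), key=sorted)

    def test_invalid_threshold_rejected(self):
        with pytest.raises(ValueError):
            merge_overlapping([], threshold=0.0)

    def test_overlap_and_jaccard_measures(self):
        a, b = frozenset("ABCD"), frozenset("CDE")
        assert overlap_coefficient(a, b) == pytest.approx(2 / 3)
        assert jaccard(a, b) == pytest.approx(2 / 5)


class TestSplit:
    def test_single_cycle_unchanged(self):
        g = digraph(
            [("A", S), ("R1", R), ("B", S), ("R2", R)],
            [("A", "R1"), ("R1", "B"), ("B", "R2"), ("R2", "A")],
        )
        sn = SubNetwork("m", frozenset(g.nodes))
        assert split_to_unique_cycle(sn, g) == [sn]

    def test_two_cycles_joined_by_path_split(self):
        nodes = [("A", S), ("R1", R), ("B", S), ("R2", R),
                 ("C", S), ("R3", R), ("D", S), ("R4", R), ("Rmid", R)]
        edges = [
            ("A", "R1"), ("R1", "B"), ("B", "R2"), ("R2", "A"),  # cycle 1
            ("C", "R3"), ("R3", "D"), ("D", "R4"), ("R4", "C"),  # cycle 2
            ("B", "Rmid"), ("Rmid", "C"),  # 2-hop connector
        ]
        g = digraph(nodes, edges)
        parts = split_to_unique_cycle(SubNetwork("m", frozenset(g.nodes)), g)
        assert len(parts) == 2
        memberships = {frozenset(p.nodes - {"Rmid"}) for p in parts}
        assert frozenset({"A", "R1", "B", "R2"}) in memberships
        assert frozenset({"C", "R3", "D", "R4"}) in memberships

    def test_acyclic_subnet_returned_unchanged(self):
        g = digraph([("A", S), ("R1", R), ("B", S)], [("A", "R1"), ("R1", "B")])
        sn = SubNetwork("m", frozenset(g.nodes))
        assert split_to_unique_cycle(sn, g) == [sn]


class TestModulesEndToEnd:
    def test_single_subnet_graph_all_defining(self, tiny_model):
        g = build_reaction_graph(tiny_model)
        modules, modmap, report = decompose(g, tiny_model)
        [m] = [mod for mod in modules if "A" in mod.defining]
        assert "B" in m.defining and "R1" in m.defining

    @pytest.mark.parametrize("seed", [11, 42])
    def test_planted_module_recovery(self, seed):
        from sigmapnet import GeneratorSpec

        spec = GeneratorSpec(
            n_modules=4, molecules_per_module=(3, 6), tf_layer_size=1, seed=seed
        )
        model, truth = generate_map(spec)
        g = prune_tf_downstream(build_reaction_graph(model), set(truth.tf_ids))
        modules, modmap, report = decompose(g, model)
        assert len(modules) == spec.n_modules
        assert report.complete
        # roles: no node defining twice, defining disjoint from incoming/outgoing
        seen = set()
        for m in modules:
            assert not (m.defining & seen)
            seen |= m.defining
            assert not (m.defining & m.incoming) and not (m.defining & m.outgoing)
            assert m.defining
        # conservation: defining union + shared leftovers covers the core
        core, _, _, _ = strongly_connected_core(g)
        shared = core.nodes - seen
        assert seen | shared == core.nodes

    def test_projected_edges_equal_planted_truth(self):
        from sigmapnet import GeneratorSpec

        spec = GeneratorSpec(n_modules=4, molecules_per_module=(3, 6),
                             bridge_density=0.2, tf_layer_size=0, seed=5)
        model, truth = generate_map(spec)
        g = build_reaction_graph(model)
        modules, modmap, _ = decompose(g, model)
        # map module names back to planted indices via their hub species
        name_to_idx = {}
        by_id = model.species_by_id()
        for m in modules:
            refs = {by_id[n].protein_reference for n in m.defining if n in by_id}
            for idx, mols in truth.module_molecules.items():
                if refs & mols:
                    name_to_idx[m.name] = idx
        projected = {
            (name_to_idx[a], name_to_idx[b], sign)
            for a, b, sign in modmap.inter_module_edges
        }
        assert projected == truth.inter_module_arcs

    def test_projection_simple_activation(self):
        g = digraph(
            [("X", S), ("RY", R), ("Y", S)],
            [("RY", "Y")],
        )
        g.add_edge("X", "RY", roles=frozenset({"MODIFIER"}), sign="ACTIVATION")
        m1 = Module("M1", defining=frozenset({"X"}), incoming=frozenset(), outgoing=frozenset({"RY"}))
        m2 = Module("M2", defining=frozenset({"Y", "RY"}), incoming=frozenset(), outgoing=frozenset())
        mm = modular_projection([m1, m2], g)
        assert mm.inter_module_edges == {("M1", "M2", "ACTIVATION")}

    def test_projection_no_cross_arcs(self):
        g = digraph([("X", S), ("R1", R)], [("X", "R1")])
        m1 = Module("M1", frozenset({"X", "R1"}), frozenset(), frozenset())
        m2 = Module("M2", frozenset(), frozenset(), frozenset())
        assert modular_projection([m1, m2], g).inter_module_edges == set()


class TestCompleteness:
    def test_full_cover_is_empty_report(self):
        g = digraph([("A", S), ("R1", R)], [("A", "R1")])
        mods = [Module("m", frozenset({"A", "R1"}), frozenset(), frozenset())]
        assert completeness_check(mods, g).complete

    def test_deleted_node_is_reported_with_its_edges(self):
        g = digraph([("A", S), ("R1", R), ("B", S)], [("A", "R1"), ("R1", "B")])
        mods = [Module("m", frozenset({"A", "R1"}), frozenset(), frozenset())]
        report = completeness_check(mods, g)
        assert report.missing_nodes == {"B"}
        assert report.missing_edges == {("R1", "B")}
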