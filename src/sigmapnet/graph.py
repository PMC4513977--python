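"""Directed bipartite species-reaction graph and its topology statistics.

Process-description maps are naturally bipartite: species and reactions are
both nodes, reactant and modifier arcs enter reactions, product arcs leave
them.  Topology statistics (degree, closeness, hubs) are computed on the
undirected view of this graph.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx

from .model import MapModel, ModifierSign, ModelIntegrityError

SPECIES = "SPECIES"
REACTION = "REACTION"


def build_reaction_graph(model: MapModel) -> nx.DiGraph:
    """One node per species and per reaction; one arc per reactant, product
    or modifier relation.  A species playing several roles toward the same
    reaction in the same direction keeps a single edge with merged roles.

    Node attributes: ``kind`` (SPECIES/REACTION), ``label``.
    Edge attributes: ``roles`` (frozenset of REACTANT/PRODUCT/MODIFIER) and
    ``sign`` (modifier sign, NONE otherwise).
    """
    g = nx.DiGraph(name=model.name)
    for s in model.species:
        g.add_node(s.species_id, kind=SPECIES, label=s.display_name)
    for r in model.reactions:
        g.add_node(r.reaction_id, kind=REACTION, label=r.reaction_class.value)
        for sid in r.participant_ids():
            if sid not in g or g.nodes[sid].get("kind") != SPECIES:
                raise ModelIntegrityError(
                    f"reaction {r.reaction_id} references unknown species {sid!r}"
                )
        for sid in r.reactants:
            _merge_edge(g, sid, r.reaction_id, "REACTANT", "NONE")
        for sid in r.products:
            _merge_edge(g, r.reaction_id, sid, "PRODUCT", "NONE")
        for sid, sign in r.modifiers:
            _merge_edge(g, sid, r.reaction_id, "MODIFIER", sign.value)
    return g


def _merge_edge(g: nx.DiGraph, u: str, v: str, role: str, sign: str) -> None:
    if g.has_edge(u, v):
        data = g.edges[u, v]
        data["roles"] = data["roles"] | {role}
        if sign != "NONE":
            data["sign"] = sign
    else:
        g.add_edge(u, v, roles=frozenset({role}), sign=sign)


def species_nodes(g: nx.DiGraph) -> set[str]:
    return {n for n, k in g.nodes(data="kind") if k == SPECIES}


def reaction_nodes(g: nx.DiGraph) -> set[str]:
    return {n for n, k in g.nodes(data="kind") if k == REACTION}


def assert_bipartite(g: nx.DiGraph) -> None:
    for u, v in g.edges:
        if g.nodes[u]["kind"] == g.nodes[v]["kind"]:
            raise ModelIntegrityError(f"edge {u}->{v} joins two {g.nodes[u]['kind']} nodes")


def prune_tf_downstream(g: nx.DiGraph, tf_ids: set[str]) -> nx.DiGraph:
    """Remove the transcription-target layer downstream of the given
    transcription-factor species.

    A node is removed when every directed path reaching it from the rest of
    the map passes through a TF node (descendants of the TFs minus nodes
    reachable without traversing any TF).  Nodes left with zero degree by
    that removal — typically target genes that only fed removed
    transcription reactions — are dropped as well.  The TF nodes themselves
    are always kept.  Idempotent.
    """
    for t in tf_ids:
        if t in g and g.nodes[t].get("kind") == REACTION:
            raise ValueError(f"tf id {t!r} is a reaction node, expected species")
    tf_present = {t for t in tf_ids if t in g}
    if not tf_present:
        return g.copy()

    desc: set[str] = set()
    anc: set[str] = set()
    for t in tf_present:
        desc |= nx.descendants(g, t)
        anc |= nx.ancestors(g, t)
    # strictly downstream: reachable from a TF with no feedback path to any
    # TF (nodes inside regulatory loops with the TFs are part of the map
    # core, not of the transcription-target layer)
    strict = desc - anc - tf_present

    # keep anything still reachable from the rest of the map while never
    # traversing a TF node; a witness must itself be anchored outside the
    # downstream layer (a target gene whose only link is its transcription
    # reaction is part of the layer, not an outside path into it)
    g_minus = g.subgraph(set(g.nodes) - tf_present)
    blocked = strict | tf_present
    sources = {
        v
        for v in set(g_minus.nodes) - strict
        if any(
            nb not in blocked
            for nb in set(g.predecessors(v)) | set(g.successors(v))
        )
    }
    reachable = set(sources)
    for s in sources:
        reachable |= nx.descendants(g_minus, s)

    removed = strict - reachable
    out = g.subgraph(set(g.nodes) - removed).copy()
    newly_isolated = {
        n for n in out.nodes
        if out.degree(n) == 0 and g.degree(n) > 0 and n not in tf_present
    }
    out.remove_nodes_from(newly_isolated)
    return out


@dataclass
class TopologySummary:
    degree_by_node: dict[str, int]
    degree_histogram: dict[int, int]
    closeness_by_node: dict[str, float]
    hubs: list[str]
    hub_threshold: int = 5
    kind_by_node: dict[str, str] = field(default_factory=dict)

    def to_rows(self):
        """(node_id, kind, degree, closeness, is_hub) rows, degree-sorted."""
        hubset = set(self.hubs)
        rows = [
            (
                n,
                self.kind_by_node.get(n, ""),
                self.degree_by_node[n],
                self.closeness_by_node[n],
                n in hubset,
            )
            for n in self.degree_by_node
        ]
        rows.sort(key=lambda r: (-r[2], r[0]))
        return rows


def topology_summary(g: nx.DiGraph, hub_threshold: int = 5) -> TopologySummary:
    """Degree, closeness and hub statistics on the undirected view.

    Closeness uses the component-size-normalised (Wasserman-Faust) form so
    values are comparable across a disconnected graph and lie in [0, 1];
    isolated nodes get 0.  Hubs are the nodes with degree strictly greater
    than ``hub_threshold``, sorted by descending degree then name.
    """
    ug = nx.Graph(g)
    degree = {n: d for n, d in ug.degree()}
    hist: dict[int, int] = {}
    for d in degree.values():
        hist[d] = hist.get(d, 0) + 1
    closeness = nx.closeness_centrality(ug, wf_improved=True)
    hubs = sorted(
        (n for n, d in degree.items() if d > hub_threshold),
        key=lambda n: (-degree[n], n),
    )
    return TopologySummary(
        degree_by_node=degree,
        degree_histogram=dict(sorted(hist.items())),
        closeness_by_node=closeness,
        hubs=hubs,
        hub_threshold=hub_threshold,
        kind_by_node={n: g.nodes[n].get("kind", "") for n in g.nodes},
    )
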