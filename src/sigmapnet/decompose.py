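"""Modular decomposition of the bipartite map graph.

The map's strongly connected component — its central cyclic motif — is
split into material components (all states of one molecule plus their
incident reactions), overlapping components are merged, over-merged
sub-networks are re-split until each contains a unique cyclic motif, and
the survivors become modules with defining / incoming / outgoing node
roles.  Finally the map is projected onto a signed module-level network.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx

from .graph import REACTION, SPECIES
from .model import MapModel

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SubNetwork:
    name: str
    nodes: frozenset[str]

    def __len__(self) -> int:
        return len(self.nodes)


@dataclass
class Module:
    name: str
    defining: frozenset[str]
    incoming: frozenset[str]
    outgoing: frozenset[str]
    outcome_annotations: tuple[str, ...] = ()

    @property
    def nodes(self) -> frozenset[str]:
        return self.defining | self.incoming | self.outgoing


@dataclass
class ModularMap:
    modules: list[Module]
    inter_module_edges: set[tuple[str, str, str]] = field(default_factory=set)


# ---------------------------------------------------------------------------


def strongly_connected_core(
    g: nx.DiGraph,
) -> tuple[SubNetwork, set[str], set[str], set[str]]:
    """Largest strongly connected component plus its periphery.

    Returns ``(core, upstream, downstream, detached)``: upstream nodes have
    a directed path into the core but none from it, downstream the
    converse, detached neither.  An acyclic graph yields an empty core with
    everything detached.
    """
    sccs = [c for c in nx.strongly_connected_components(g) if len(c) > 1]
    if not sccs:
        return SubNetwork("core", frozenset()), set(), set(), set(g.nodes)
    core = max(sccs, key=lambda c: (len(c), tuple(sorted(c))))
    seed = next(iter(core))
    down = (nx.descendants(g, seed) | core) - core
    up = (nx.ancestors(g, seed) | core) - core
    detached = set(g.nodes) - core - up - down
    return SubNetwork("core", frozenset(core)), up, down, detached


def material_components(
    core: SubNetwork, model: MapModel, graph: nx.DiGraph
) -> list[SubNetwork]:
    """Group core species by molecule (shared protein_reference, or complex
    membership) together with their incident core reactions.

    Species without any molecule symbol are attached to the component of
    every incident reaction (logged); sub-networks may overlap on shared
    reaction nodes.
    """
    if not core.nodes:
        raise ValueError("material_components requires a nonempty core")
    by_id = model.species_by_id()
    groups: dict[str, set[str]] = {}
    orphans: list[str] = []
    for n in sorted(core.nodes):
        sp = by_id.get(n)
        if sp is None:  # reaction node
            continue
        symbols = set()
        if sp.protein_reference:
            symbols.add(sp.protein_reference)
        symbols.update(sp.complex_members)
        if symbols:
            for sym in symbols:
                groups.setdefault(sym, set()).add(n)
        else:
            orphans.append(n)

    sub = graph.subgraph(core.nodes)
    comps: dict[str, set[str]] = {}
    for sym, members in groups.items():
        nodes = set(members)
        for m in members:
            for nb in set(sub.predecessors(m)) | set(sub.successors(m)):
                if graph.nodes[nb]["kind"] == REACTION:
                    nodes.add(nb)
        comps[sym] = nodes

    for n in orphans:
        incident = {
            nb
            for nb in set(sub.predecessors(n)) | set(sub.successors(n))
            if graph.nodes[nb]["kind"] == REACTION
        }
        hit = False
        for sym, nodes in comps.items():
            if incident & nodes:
                nodes.add(n)
                hit = True
        if not hit:
            comps[f"orphan:{n}"] = {n} | incident
        logger.info("species %s has no molecule symbol; attached by incidence", n)

    return [SubNetwork(sym, frozenset(nodes)) for sym, nodes in sorted(comps.items())]


def overlap_coefficient(a: frozenset, b: frozenset) -> float:
    if not a or not b:
        return 0.0
    return len(a & b) / min(len(a), len(b))


def jaccard(a: frozenset, b: frozenset) -> float:
    return len(a & b) / len(a | b) if a | b else 0.0


def merge_overlapping(
    subnets: list[SubNetwork],
    threshold: float = 0.5,
    measure: str = "overlap",
) -> list[SubNetwork]:
    """Merge sub-networks sharing >= ``threshold`` of the smaller one.

    ``measure`` is ``overlap`` (|A∩B|/min, default) or ``jaccard``.  Pairs
    are scanned in a fixed order (descending size, then name) and merging
    repeats to a fixed point, so the result is order-independent by
    construction.  Each merge reduces the count by one, hence termination.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    score = overlap_coefficient if measure == "overlap" else jaccard
    pool = list(subnets)
    merged = True
    while merged:
        merged = False
        pool.sort(key=lambda s: (-len(s), s.name))
        for i in range(len(pool)):
            for j in range(i + 1, len(pool)):
                if score(pool[i].nodes, pool[j].nodes) >= threshold:
                    a, b = pool[i], pool[j]
                    name = a.name if len(a) >= len(b) else b.name
                    pool[i] = SubNetwork(name, a.nodes | b.nodes)
                    del pool[j]
                    merged = True
                    break
            if merged:
                break
    return pool


def split_to_unique_cycle(
    subnet: SubNetwork, graph: nx.DiGraph
) -> list[SubNetwork]:
    """Split a sub-network until it holds exactly one nontrivial cyclic motif.

    If the induced subgraph has more than one strongly connected component
    of size >= 2, one sub-network is produced per such component and every
    acyclic node is assigned to the component it reaches (or is reached
    from) in the fewest hops; ties go to the larger component, then to the
    lexicographically first.  A cycle-free sub-network is returned
    unchanged (callers may flag it acyclic).
    """
    sub = graph.subgraph(subnet.nodes)
    cores = sorted(
        (c for c in nx.strongly_connected_components(sub) if len(c) > 1),
        key=lambda c: (-len(c), tuple(sorted(c))),
    )
    if len(cores) <= 1:
        return [subnet]
    und = nx.Graph(sub)
    assignment: dict[str, int] = {}
    for idx, core in enumerate(cores):
        for n in core:
            assignment[n] = idx
    free = [n for n in subnet.nodes if n not in assignment]
    for n in free:
        dists = nx.single_source_shortest_path_length(und, n)
        best = None  # (hops, -len(core), idx)
        for idx, core in enumerate(cores):
            reach = [dists[c] for c in core if c in dists]
            if reach:
                key = (min(reach), -len(cores[idx]), idx)
                if best is None or key < best:
                    best = key
        assignment[n] = best[2] if best is not None else 0
    out = []
    for idx in range(len(cores)):
        nodes = frozenset(n for n, a in assignment.items() if a == idx)
        out.append(SubNetwork(f"{subnet.name}.{idx}", nodes))
    return out


def assemble_modules(
    subnets: list[SubNetwork],
    graph: nx.DiGraph,
    upstream: set[str] | None = None,
    downstream: set[str] | None = None,
    names: dict[str, str] | None = None,
    outcome_annotations: dict[str, tuple[str, ...]] | None = None,
) -> list[Module]:
    """Turn sub-networks into role-annotated modules.

    Unconnected nodes (zero edges inside their sub-network) are removed;
    *defining* nodes belong to exactly one sub-network; external nodes with
    arcs into (out of) the defining set are *incoming* (*outgoing*).  Each
    module is named after its highest-degree defining species, overridable
    through ``names``.
    """
    cleaned: list[SubNetwork] = []
    for sn in subnets:
        sub = graph.subgraph(sn.nodes)
        keep = frozenset(n for n in sn.nodes if sub.degree(n) > 0)
        if not keep:
            logger.warning("sub-network %s empty after unconnected-node removal", sn.name)
            continue
        cleaned.append(SubNetwork(sn.name, keep))

    membership: dict[str, int] = {}
    shared: set[str] = set()
    for i, sn in enumerate(cleaned):
        for n in sn.nodes:
            if n in membership:
                shared.add(n)
            else:
                membership[n] = i

    ug = nx.Graph(graph)
    modules: list[Module] = []
    used_names: set[str] = set()
    for i, sn in enumerate(cleaned):
        defining = frozenset(
            n for n in sn.nodes if n not in shared
        )
        if not defining:
            logger.warning("sub-network %s has no defining nodes; dropped", sn.name)
            continue
        incoming = frozenset(
            u for d in defining for u in graph.predecessors(d) if u not in defining
        )
        outgoing = frozenset(
            v for d in defining for v in graph.successors(d)
            if v not in defining and v not in incoming
        )
        def_species = [
            n for n in defining if graph.nodes[n].get("kind") == SPECIES
        ]
        if def_species:
            center = max(def_species, key=lambda n: (ug.degree(n), n))
            label = graph.nodes[center].get("label") or center
        else:
            label = sn.name
        name = (names or {}).get(sn.name, label)
        base, k = name, 2
        while name in used_names:
            name, k = f"{base}#{k}", k + 1
        used_names.add(name)
        modules.append(
            Module(
                name=name,
                defining=defining,
                incoming=incoming,
                outgoing=outgoing,
                outcome_annotations=(outcome_annotations or {}).get(name, ()),
            )
        )
    return modules


def modular_projection(modules: list[Module], graph: nx.DiGraph) -> ModularMap:
    """Project the map onto modules with signed activation/inhibition edges.

    Module A activates (inhibits) module B when a defining node of A is an
    activating (inhibitory) modifier of, or produces, a defining or
    incoming node of B.  Opposite-sign evidence yields both edges.
    """
    owner: dict[str, list[Module]] = {}
    for m in modules:
        for n in m.defining | m.incoming:
            owner.setdefault(n, []).append(m)
    def_of: dict[str, Module] = {}
    for m in modules:
        for n in m.defining:
            def_of[n] = m

    edges: set[tuple[str, str, str]] = set()
    for u, v, data in graph.edges(data=True):
        src = def_of.get(u)
        if src is None:
            continue
        roles = data.get("roles", frozenset())
        if "MODIFIER" in roles:
            sign = data.get("sign", "UNKNOWN")
            sign = "ACTIVATION" if sign not in ("ACTIVATION", "INHIBITION") else sign
        elif "PRODUCT" in roles:
            sign = "ACTIVATION"
        else:
            continue
        for tgt in owner.get(v, []):
            if tgt is not src:
                edges.add((src.name, tgt.name, sign))
    return ModularMap(modules=list(modules), inter_module_edges=edges)


@dataclass
class CompletenessReport:
    missing_nodes: frozenset[str]
    missing_edges: frozenset[tuple[str, str]]

    @property
    def complete(self) -> bool:
        return not self.missing_nodes and not self.missing_edges


def completeness_check(modules: list[Module], graph: nx.DiGraph) -> CompletenessReport:
    """Merge the modules back and compare with the graph they came from.

    A node is covered when it appears in any module (any role); an edge is
    covered when both endpoints lie inside one module's node set.  An empty
    report certifies a complete cover.
    """
    covered: set[str] = set()
    for m in modules:
        covered |= m.nodes
    missing_nodes = frozenset(set(graph.nodes) - covered)
    missing_edges = set()
    module_nodes = [m.nodes for m in modules]
    for u, v in graph.edges:
        if not any(u in ns and v in ns for ns in module_nodes):
            missing_edges.add((u, v))
    return CompletenessReport(missing_nodes, frozenset(missing_edges))


def decompose(
    graph: nx.DiGraph,
    model: MapModel,
    overlap_threshold: float = 0.5,
    measure: str = "overlap",
    names: dict[str, str] | None = None,
) -> tuple[list[Module], ModularMap, CompletenessReport]:
    """Full decomposition: core -> material components -> merge -> split ->
    modules -> signed modular projection -> completeness check."""
    core, up, down, _ = strongly_connected_core(graph)
    if not core.nodes:
        return [], ModularMap(modules=[]), completeness_check([], graph)
    comps = material_components(core, model, graph)
    merged = merge_overlapping(comps, threshold=overlap_threshold, measure=measure)
    split: list[SubNetwork] = []
    for sn in merged:
        split.extend(split_to_unique_cycle(sn, graph))
    modules = assemble_modules(split, graph, up, down, names=names)
    return modules, modular_projection(modules, graph), completeness_check(modules, graph)
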