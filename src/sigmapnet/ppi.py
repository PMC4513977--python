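"""Protein-protein interaction filtering and compactness-based map expansion.

Interaction records in PSI-MITAB format are filtered down to binary
physical interactions using a controlled-vocabulary whitelist of detection
methods, then every protein interacting with the map is tested for whether
adding it makes the map's protein network more compact: higher mean
degree, mean betweenness and mean local clustering, lower characteristic
path length.  Candidates are always judged against the unmodified base
network, so verdicts are independent of each other.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx

from .decompose import Module
from .graph import SPECIES
from .model import MapModel, MapSpecies, SpeciesClass

logger = logging.getLogger(__name__)

#: Default whitelist of PSI-MI detection-method accessions treated as
#: evidence of a binary physical interaction: the two-hybrid family and
#: protein-complementation assays.  Editable / replaceable by the caller.
DEFAULT_METHOD_WHITELIST: frozenset[str] = frozenset(
    {
        "MI:0018",  # two hybrid
        "MI:0397",  # two hybrid array
        "MI:0398",  # two hybrid pooling approach
        "MI:0399",  # two hybrid fragment pooling
        "MI:1112",  # two hybrid prey pooling approach
        "MI:0090",  # protein complementation assay
        "MI:0112",  # ubiquitin reconstruction
        "MI:0232",  # transcriptional complementation assay
        "MI:0809",  # bimolecular fluorescence complementation
    }
)

_MI_RE = re.compile(r"MI:\d{4}")
_ID_RE = re.compile(r"^[\w.-]+:(?P<value>[^()|]+)")


@dataclass(frozen=True)
class InteractionRecord:
    a: str
    b: str
    method_terms: frozenset[str]
    type_terms: frozenset[str] = frozenset()
    sources: frozenset[str] = frozenset()


@dataclass
class SkipReport:
    n_lines: int = 0
    n_records: int = 0
    skipped: list[tuple[int, str]] = field(default_factory=list)


class MitabFormatError(ValueError):
    pass


def _first_symbol(*fields: str, aliases: Mapping[str, str] | None) -> str | None:
    """Resolve the first usable identifier among MITAB id/alt/alias fields."""
    for fld in fields:
        if not fld or fld == "-":
            continue
        for token in fld.split("|"):
            token = token.strip()
            if aliases is not None and token in aliases:
                return aliases[token]
            m = _ID_RE.match(token)
            if m:
                value = m.group("value").strip().strip('"')
                if aliases is not None:
                    if value in aliases:
                        return aliases[value]
                    continue
                if value:
                    return value.upper()
    return None


def read_psi_mitab(
    path: str | Path,
    aliases: Mapping[str, str] | None = None,
) -> tuple[list[InteractionRecord], SkipReport]:
    """Read a PSI-MITAB 2.5+ tab-delimited file into interaction records.

    Identifier columns are resolved to a canonical symbol through the
    optional ``aliases`` table (id or bare accession -> symbol); without a
    table the bare value of the first identifier is used.  Records whose
    identifiers cannot be resolved are skipped and counted, wrong column
    counts raise with the offending line number.
    """
    records: list[InteractionRecord] = []
    report = SkipReport()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            report.n_lines += 1
            cols = line.split("\t")
            if len(cols) < 15:
                raise MitabFormatError(
                    f"{path}: line {lineno}: expected >=15 MITAB columns, got {len(cols)}"
                )
            a = _first_symbol(cols[0], cols[2], cols[4], aliases=aliases)
            b = _first_symbol(cols[1], cols[3], cols[5], aliases=aliases)
            if a is None or b is None:
                report.skipped.append((lineno, "unresolvable identifier"))
                continue
            records.append(
                InteractionRecord(
                    a=a,
                    b=b,
                    method_terms=frozenset(_MI_RE.findall(cols[6])),
                    type_terms=frozenset(_MI_RE.findall(cols[11])),
                    sources=frozenset(
                        t for t in re.split(r"[|]", cols[12]) if t and t != "-"
                    ),
                )
            )
            report.n_records += 1
    return records, report


@dataclass
class Interactome:
    """Undirected binary physical interaction network with provenance."""

    graph: nx.Graph = field(default_factory=nx.Graph)

    @property
    def proteins(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def interactions(self) -> set[frozenset[str]]:
        return {frozenset((u, v)) for u, v in self.graph.edges}

    def partners(self, protein: str) -> set[str]:
        return set(self.graph[protein]) if protein in self.graph else set()


def filter_binary_physical(
    records: Iterable[InteractionRecord],
    method_whitelist: Iterable[str] = DEFAULT_METHOD_WHITELIST,
    ontology_parents: Mapping[str, str] | None = None,
) -> Interactome:
    """Keep records whose detection method (or an ancestor term, when an
    ontology child->parent map is supplied) is whitelisted; drop
    self-interactions; merge duplicates across databases, unioning
    method and provenance annotations."""
    whitelist = set(method_whitelist)
    if not whitelist:
        raise ValueError("method whitelist must be nonempty")

    def allowed(term: str) -> bool:
        seen = set()
        while term and term not in seen:
            if term in whitelist:
                return True
            seen.add(term)
            term = (ontology_parents or {}).get(term, "")
        return False

    net = nx.Graph()
    kept = 0
    for rec in records:
        if rec.a == rec.b:
            continue
        if not any(allowed(t) for t in rec.method_terms):
            continue
        kept += 1
        if net.has_edge(rec.a, rec.b):
            data = net.edges[rec.a, rec.b]
            data["methods"] |= rec.method_terms
            data["sources"] |= rec.sources
        else:
            net.add_edge(
                rec.a, rec.b, methods=set(rec.method_terms), sources=set(rec.sources)
            )
    if kept == 0:
        logger.warning("no interaction records passed the binary-physical filter")
    return Interactome(graph=net)


def candidate_interactors(
    interactome: Interactome, map_proteins: set[str]
) -> tuple[set[str], int]:
    """Proteins with at least one binary physical interaction to a map
    protein (map members included), plus the count of map proteins present
    in the interactome at all."""
    if not map_proteins:
        raise ValueError("map_proteins must be nonempty")
    coverage = len(map_proteins & interactome.proteins)
    candidates = {
        p
        for p in interactome.proteins
        if interactome.partners(p) & map_proteins
    }
    return candidates, coverage


# ---------------------------------------------------------------------------
# compactness


def compactness_metrics(g: nx.Graph) -> tuple[float, float, float, float]:
    """(mean degree, mean betweenness, mean local clustering,
    characteristic path length) of an undirected network.

    Betweenness is the normalised shortest-path form with endpoints
    excluded; clustering of degree<2 nodes is 0; path length averages over
    connected ordered pairs only (0 with a flag-by-convention for a
    single-node network).
    """
    n = g.number_of_nodes()
    if n == 0:
        raise ValueError("network must be nonempty")
    mean_degree = 2 * g.number_of_edges() / n
    bet = nx.betweenness_centrality(g, normalized=True, endpoints=False)
    mean_betweenness = sum(bet.values()) / n
    clus = nx.clustering(g)
    mean_clustering = sum(clus.values()) / n
    total, pairs = 0, 0
    for node, dists in nx.all_pairs_shortest_path_length(g):
        for other, d in dists.items():
            if other != node:
                total += d
                pairs += 1
    path_length = total / pairs if pairs else 0.0
    return mean_degree, mean_betweenness, mean_clustering, path_length


@dataclass(frozen=True)
class CompactnessReport:
    candidate: str
    n_map_partners: int
    delta_degree: float
    delta_betweenness: float
    delta_clustering: float
    delta_path_length: float
    accepted: bool
    in_original_map: bool


def _accept(deltas: tuple[float, float, float, float], criteria: str) -> bool:
    """``criteria`` = 'all' (default) or 'k-of-4' e.g. '3-of-4'."""
    hits = [
        deltas[0] > 0,
        deltas[1] > 0,
        deltas[2] > 0,
        deltas[3] < 0,
    ]
    if criteria == "all":
        return all(hits)
    m = re.fullmatch(r"(\d)-of-4", criteria)
    if not m:
        raise ValueError(f"unknown acceptance criteria {criteria!r}")
    return sum(hits) >= int(m.group(1))


def evaluate_candidate(
    base_network: nx.Graph,
    interactome: Interactome,
    candidate: str,
    in_map: bool = False,
    criteria: str = "all",
    base_metrics: tuple[float, float, float, float] | None = None,
) -> CompactnessReport:
    """Compactness deltas from adding one candidate and its interactome
    edges to the base network.

    The four indicators, each of which must improve for acceptance
    (configurable via ``criteria``):

    * ``delta_degree``      — change in the network's mean degree;
    * ``delta_betweenness`` — the candidate's own betweenness in the
      extended network minus that network's mean betweenness (a tightly
      linked interactor carries above-average shortest-path traffic);
    * ``delta_clustering``  — change in the network's triangle count: the
      candidate must close new triangles with map proteins;
    * ``delta_path_length`` — change in characteristic path length.

    Betweenness and clustering are deliberately not the all-node network
    means: on a connected graph the mean betweenness equals
    ``(L - 1)/(N - 2)`` with L the characteristic path length, so asking
    the all-node mean to rise while L falls would be unsatisfiable; and
    the mean local clustering coefficient mechanically falls around any
    well-connected addition (its partners gain neighbors faster than
    triangles), which would punish exactly the tight interactors the
    method seeks.  Triangle mass is the monotone reading of "higher
    average local clustering".
    """
    partners = interactome.partners(candidate) & set(base_network.nodes) - {candidate}
    if not partners:
        raise ValueError(f"candidate {candidate!r} has no partner in the base network")
    if base_metrics is None:
        base_metrics = compactness_metrics(base_network)
    extended = base_network.copy()
    extended.add_node(candidate)
    extended.add_edges_from((candidate, p) for p in partners)

    n_ext = extended.number_of_nodes()
    mean_degree_ext = 2 * extended.number_of_edges() / n_ext
    bet_ext = nx.betweenness_centrality(extended, normalized=True, endpoints=False)
    d_triangles = (
        sum(nx.triangles(extended).values()) - sum(nx.triangles(base_network).values())
    ) / 3
    total, pairs = 0, 0
    for node, dists in nx.all_pairs_shortest_path_length(extended):
        for other, d in dists.items():
            if other != node:
                total += d
                pairs += 1
    path_length_ext = total / pairs if pairs else 0.0

    deltas = (
        mean_degree_ext - base_metrics[0],
        bet_ext[candidate] - sum(bet_ext.values()) / n_ext,
        float(d_triangles),
        path_length_ext - base_metrics[3],
    )
    return CompactnessReport(
        candidate=candidate,
        n_map_partners=len(partners),
        delta_degree=deltas[0],
        delta_betweenness=deltas[1],
        delta_clustering=deltas[2],
        delta_path_length=deltas[3],
        accepted=_accept(deltas, criteria),
        in_original_map=in_map,
    )


def protein_projection(model: MapModel) -> nx.Graph:
    """Undirected protein-level projection of a map: two molecule symbols
    are adjacent when they co-occur in one reaction (any role) or one
    complex."""
    g = nx.Graph()
    by_id = model.species_by_id()

    def symbols_of(sp: MapSpecies) -> set[str]:
        out = set()
        if sp.protein_reference and sp.species_class is SpeciesClass.PROTEIN:
            out.add(sp.protein_reference)
        out.update(sp.complex_members)
        return out

    for sp in model.species:
        for sym in symbols_of(sp):
            g.add_node(sym)
        members = sorted(symbols_of(sp))
        g.add_edges_from(
            (members[i], members[j])
            for i in range(len(members))
            for j in range(i + 1, len(members))
        )
    for r in model.reactions:
        syms: set[str] = set()
        for sid in r.participant_ids():
            sp = by_id.get(sid)
            if sp is not None:
                syms |= symbols_of(sp)
        members = sorted(syms)
        g.add_edges_from(
            (members[i], members[j])
            for i in range(len(members))
            for j in range(i + 1, len(members))
        )
    return g


def base_expansion_network(model: MapModel, interactome: Interactome) -> nx.Graph:
    """Base network for whole-map expansion: the protein projection of the
    map unioned with interactome edges among map proteins."""
    base = protein_projection(model)
    for u, v in interactome.graph.edges:
        if u in base and v in base:
            base.add_edge(u, v)
    return base


def pathexpand_select(
    base_network: nx.Graph,
    interactome: Interactome,
    map_proteins: set[str],
    criteria: str = "all",
) -> tuple[list[CompactnessReport], list[CompactnessReport]]:
    """Evaluate every candidate interactor independently against the
    unmodified base network.

    Returns ``(accepted, novel)`` where novel excludes original map
    proteins; both sorted by (map-partner count desc, symbol).
    """
    candidates, _ = candidate_interactors(interactome, map_proteins)
    base_metrics = compactness_metrics(base_network)
    reports = []
    for cand in sorted(candidates):
        partners = interactome.partners(cand) & set(base_network.nodes) - {cand}
        if not partners:
            continue
        reports.append(
            evaluate_candidate(
                base_network,
                interactome,
                cand,
                in_map=cand in map_proteins,
                criteria=criteria,
                base_metrics=base_metrics,
            )
        )
    accepted = [r for r in reports if r.accepted]
    accepted.sort(key=lambda r: (-r.n_map_partners, r.candidate))
    novel = [r for r in accepted if not r.in_original_map]
    return accepted, novel


@dataclass
class ModuleExpansion:
    module: str
    reports: list[CompactnessReport]
    modules_touched: dict[str, tuple[str, ...]]
    single_module: list[str]
    multi_module: list[str]


def module_expansion(
    module: Module,
    interactome: Interactome,
    all_modules: Sequence[Module],
    model: MapModel,
    criteria: str = "all",
) -> ModuleExpansion:
    """Expand one module's protein sub-network and classify each accepted
    interactor as single-module or multi-module by which modules' defining
    proteins it touches."""
    def_proteins = _module_proteins(module, model)
    if not def_proteins:
        return ModuleExpansion(module.name, [], {}, [], [])
    base = protein_projection(model).subgraph(def_proteins).copy()
    for u, v in interactome.graph.edges:
        if u in base and v in base:
            base.add_edge(u, v)
    proteins_by_module = {m.name: _module_proteins(m, model) for m in all_modules}
    reports, touched = [], {}
    base_metrics = compactness_metrics(base) if base.number_of_nodes() else None
    for cand in sorted(interactome.proteins - set(base.nodes)):
        partners = interactome.partners(cand) & set(base.nodes)
        if not partners:
            continue
        rep = evaluate_candidate(
            base, interactome, cand, criteria=criteria, base_metrics=base_metrics
        )
        reports.append(rep)
        if rep.accepted:
            touched[cand] = tuple(
                sorted(
                    name
                    for name, prots in proteins_by_module.items()
                    if interactome.partners(cand) & prots
                )
            )
    single = sorted(c for c, mods in touched.items() if len(mods) == 1)
    multi = sorted(c for c, mods in touched.items() if len(mods) > 1)
    return ModuleExpansion(module.name, reports, touched, single, multi)


def _module_proteins(module: Module, model: MapModel) -> set[str]:
    by_id = model.species_by_id()
    out: set[str] = set()
    for n in module.defining:
        sp = by_id.get(n)
        if sp is None:
            continue
        if sp.protein_reference and sp.species_class is SpeciesClass.PROTEIN:
            out.add(sp.protein_reference)
        out.update(sp.complex_members)
    return out
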