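"""Synthetic signaling maps and interactomes with known ground truth.

The map generator plants modules shaped like the kinase-hub motifs of real
signaling maps: each module has one hub molecule that drives an
activation/deactivation cycle with every member molecule and catalyses the
members' state cycles.  This wiring gives the map (i) a single strongly
connected core spanning all modules (modules are chained in a ring of
signed cross-talk arcs, plus random extra arcs), (ii) material components
that overlap their hub's component by at least half — exactly the
structure the >=50 % merge step of the decomposition reassembles — and
(iii) a right-skewed, hub-dominated degree distribution.  Transcription
tails (TF -> transcription -> RNA -> translation -> protein) hang off the
core and are what the TF-pruning step removes.

The interactome generator wires planted "tight" candidates to a stated
fraction of map proteins and decoys to only 1-2 partners, writing standard
PSI-MITAB 2.5 lines; a fraction of decoy records deliberately carries
non-whitelisted detection methods to exercise the binary-physical filter.

Both generators are byte-deterministic given a spec and seed.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field
from pathlib import Path

from pydantic import BaseModel, Field, model_validator

from .model import (
    MapModel,
    MapReaction,
    MapSpecies,
    ModifierSign,
    ReactionClass,
    SpeciesClass,
)


class GeneratorSpec(BaseModel):
    """Parameters of the planted-structure generators (defaults = the
    frozen benchmark world)."""

    n_modules: int = Field(default=8, ge=1)
    molecules_per_module: tuple[int, int] = (6, 14)
    states_per_molecule: tuple[int, int] = (1, 4)
    intra_module_cycle: bool = True
    bridge_density: float = Field(default=0.05, ge=0.0, le=1.0)
    tf_layer_size: int = Field(default=4, ge=0)
    n_planted_candidates: int = Field(default=10, ge=0)
    planted_wiring_fraction: float = Field(default=0.3, ge=0.0, le=1.0)
    n_decoys: int = Field(default=200, ge=0)
    decoy_degree: tuple[int, int] = (1, 2)
    decoy_offmethod_fraction: float = Field(default=0.1, ge=0.0, le=1.0)
    seed: int = 0

    @model_validator(mode="after")
    def _feasible(self) -> "GeneratorSpec":
        for name in ("molecules_per_module", "states_per_molecule", "decoy_degree"):
            lo, hi = getattr(self, name)
            if lo < 1 or hi < lo:
                raise ValueError(f"{name} must be a 1-based (lo, hi) range")
        if self.intra_module_cycle and self.molecules_per_module[0] < 2:
            raise ValueError(
                "an intra-module cycle needs at least 2 molecules per module"
            )
        if self.tf_layer_size > self.n_modules:
            raise ValueError("tf_layer_size cannot exceed n_modules")
        return self


@dataclass
class MapGroundTruth:
    """Everything needed to score recovery without re-reading the generator."""

    module_molecules: dict[int, frozenset[str]]
    module_species: dict[int, frozenset[str]]
    module_reactions: dict[int, frozenset[str]]
    tf_ids: list[str]
    tail_nodes: frozenset[str]
    inter_module_arcs: set[tuple[int, int, str]]
    n_species: int = 0
    n_reactions: int = 0
    n_arcs: int = 0
    n_proteins: int = 0

    def as_dict(self) -> dict:
        return {
            "module_molecules": {k: sorted(v) for k, v in self.module_molecules.items()},
            "module_species": {k: sorted(v) for k, v in self.module_species.items()},
            "module_reactions": {k: sorted(v) for k, v in self.module_reactions.items()},
            "tf_ids": list(self.tf_ids),
            "tail_nodes": sorted(self.tail_nodes),
            "inter_module_arcs": sorted(self.inter_module_arcs),
            "n_species": self.n_species,
            "n_reactions": self.n_reactions,
            "n_arcs": self.n_arcs,
            "n_proteins": self.n_proteins,
        }


def generate_map(spec: GeneratorSpec) -> tuple[MapModel, MapGroundTruth]:
    """Generate a planted-module signaling map (see module docstring).

    Structural rules that make the planted truth recoverable:

    * every member molecule shares its state-cycle reactions and its two
      hub-coupling reactions with the hub's material component, so the
      member/hub overlap coefficient is always >= 1/2;
    * each species sources at most one cross-talk arc and all cross-talk
      arcs target member->hub return reactions, keeping cross-module
      component overlap strictly below 1/2;
    * module hubs are chained in a ring of cross-talk arcs, so the core is
      a single strongly connected component covering every module.
    """
    rng = random.Random(spec.seed)
    species: list[MapSpecies] = []
    reactions: list[MapReaction] = []
    truth = MapGroundTruth({}, {}, {}, [], frozenset(), set())

    hub_anchor: dict[int, str] = {}
    return_rxns: dict[int, list[str]] = {}
    module_species_syms: dict[int, list[str]] = {}
    bridge_sources_used: set[str] = set()

    def pmid() -> tuple[str, ...]:
        return (f"PMID:{rng.randint(1000000, 9999999)}",)

    for mi in range(spec.n_modules):
        n_mol = rng.randint(*spec.molecules_per_module)
        mol_syms = [f"M{mi}HUB"] + [f"M{mi}P{k}" for k in range(1, n_mol)]
        sp_ids: set[str] = set()
        rx_ids: set[str] = set()
        return_rxns[mi] = []
        module_species_syms[mi] = mol_syms

        hub_id = f"s_m{mi}_hub"
        hub_anchor[mi] = hub_id
        species.append(
            MapSpecies(
                species_id=hub_id,
                display_name=f"M{mi}HUB",
                species_class=SpeciesClass.PROTEIN,
                protein_reference=f"M{mi}HUB",
                compartment="cytosol",
                state_tags=frozenset({"active"}),
            )
        )
        sp_ids.add(hub_id)

        for k, sym in enumerate(mol_syms[1:], start=1):
            n_states = rng.randint(*spec.states_per_molecule)
            state_ids = [f"s_m{mi}_p{k}_{j}" for j in range(n_states)]
            for j, sid in enumerate(state_ids):
                species.append(
                    MapSpecies(
                        species_id=sid,
                        display_name=sym,
                        species_class=SpeciesClass.PROTEIN,
                        protein_reference=sym,
                        compartment="cytosol",
                        state_tags=frozenset({f"state{j}"} if j else set()),
                    )
                )
                sp_ids.add(sid)
            # state cycle catalysed by the hub (s1 -> ... -> sn -> s1)
            if n_states >= 2:
                for j in range(n_states):
                    rid = f"r_m{mi}_p{k}_st{j}"
                    reactions.append(
                        MapReaction(
                            reaction_id=rid,
                            reaction_class=ReactionClass.STATE_TRANSITION,
                            reactants=(state_ids[j],),
                            products=(state_ids[(j + 1) % n_states],),
                            modifiers=((hub_id, ModifierSign.ACTIVATION),),
                            annotations=pmid(),
                        )
                    )
                    rx_ids.add(rid)
            if spec.intra_module_cycle:
                # hub <-> member activation/deactivation loop
                out_id, in_id = f"r_m{mi}_p{k}_act", f"r_m{mi}_p{k}_ret"
                reactions.append(
                    MapReaction(
                        reaction_id=out_id,
                        reaction_class=ReactionClass.STATE_TRANSITION,
                        reactants=(hub_id,),
                        products=(state_ids[0],),
                        annotations=pmid(),
                    )
                )
                reactions.append(
                    MapReaction(
                        reaction_id=in_id,
                        reaction_class=ReactionClass.STATE_TRANSITION,
                        reactants=(state_ids[0],),
                        products=(hub_id,),
                        annotations=pmid(),
                    )
                )
                rx_ids.update((out_id, in_id))
                return_rxns[mi].append(in_id)

        # one heterodimer association/dissociation loop per module (hub
        # catalysed, so the complex stays inside the module's cyclic motif)
        if spec.intra_module_cycle and n_mol >= 3:
            a_sym, b_sym = mol_syms[1], mol_syms[2]
            a_id, b_id = f"s_m{mi}_p1_0", f"s_m{mi}_p2_0"
            cx_id = f"s_m{mi}_cx"
            species.append(
                MapSpecies(
                    species_id=cx_id,
                    display_name=f"{a_sym}:{b_sym}",
                    species_class=SpeciesClass.COMPLEX,
                    compartment="cytosol",
                    complex_members=(a_sym, b_sym),
                )
            )
            sp_ids.add(cx_id)
            asc_id, dis_id = f"r_m{mi}_asc", f"r_m{mi}_dis"
            reactions.append(
                MapReaction(
                    reaction_id=asc_id,
                    reaction_class=ReactionClass.HETERODIMER_ASSOCIATION,
                    reactants=(a_id, b_id),
                    products=(cx_id,),
                    modifiers=((hub_id, ModifierSign.ACTIVATION),),
                    annotations=pmid(),
                )
            )
            reactions.append(
                MapReaction(
                    reaction_id=dis_id,
                    reaction_class=ReactionClass.DISSOCIATION,
                    reactants=(cx_id,),
                    products=(a_id, b_id),
                    modifiers=((hub_id, ModifierSign.ACTIVATION),),
                    annotations=pmid(),
                )
            )
            rx_ids.update((asc_id, dis_id))

        truth.module_molecules[mi] = frozenset(mol_syms)
        truth.module_species[mi] = frozenset(sp_ids)
        truth.module_reactions[mi] = frozenset(rx_ids)

    # --- cross-talk arcs: deterministic ring + random extras -----------------
    id_to_index = {s.species_id: i for i, s in enumerate(species)}
    degree: dict[str, int] = {s.species_id: 1 for s in species}
    for r in reactions:
        for sid in r.participant_ids():
            degree[sid] = degree.get(sid, 1) + 1

    rx_by_id = {r.reaction_id: i for i, r in enumerate(reactions)}

    def add_bridge(src_module: int, dst_module: int, source_id: str) -> None:
        sign = rng.choice([ModifierSign.ACTIVATION, ModifierSign.INHIBITION])
        target = rng.choice(sorted(return_rxns[dst_module]))
        idx = rx_by_id[target]
        r = reactions[idx]
        reactions[idx] = MapReaction(
            reaction_id=r.reaction_id,
            reaction_class=r.reaction_class,
            reactants=r.reactants,
            products=r.products,
            modifiers=r.modifiers + ((source_id, sign),),
            annotations=r.annotations,
        )
        bridge_sources_used.add(source_id)
        truth.inter_module_arcs.add((src_module, dst_module, sign.value))

    if spec.n_modules > 1:
        for mi in range(spec.n_modules):
            add_bridge(mi, (mi + 1) % spec.n_modules, hub_anchor[mi])
        for mi in range(spec.n_modules):
            for mj in range(spec.n_modules):
                if mi == mj or (mj == (mi + 1) % spec.n_modules):
                    continue
                if rng.random() >= spec.bridge_density:
                    continue
                # preferential attachment: degree-weighted source choice,
                # each species sourcing at most one arc
                pool = [
                    sid
                    for sid in sorted(truth.module_species[mi])
                    if sid not in bridge_sources_used
                ]
                if not pool:
                    continue
                weights = [degree[sid] for sid in pool]
                source = rng.choices(pool, weights=weights, k=1)[0]
                add_bridge(mi, mj, source)

    # --- transcription-factor tails -----------------------------------------
    tf_ids: list[str] = []
    tail_nodes: set[str] = set()
    for t in range(spec.tf_layer_size):
        tf = hub_anchor[t]
        tf_ids.append(tf)
        gene_id, rna_id, prot_id = f"s_tf{t}_gene", f"s_tf{t}_rna", f"s_tf{t}_prot"
        target_sym = f"TFTGT{t}"
        species.extend(
            [
                MapSpecies(gene_id, target_sym, SpeciesClass.GENE, "", "nucleus"),
                MapSpecies(rna_id, target_sym, SpeciesClass.RNA, target_sym, "nucleus"),
                MapSpecies(prot_id, target_sym, SpeciesClass.PROTEIN, target_sym, "cytosol"),
            ]
        )
        tsc_id, tsl_id = f"r_tf{t}_tsc", f"r_tf{t}_tsl"
        reactions.append(
            MapReaction(
                reaction_id=tsc_id,
                reaction_class=ReactionClass.TRANSCRIPTION,
                reactants=(gene_id,),
                products=(rna_id,),
                modifiers=((tf, ModifierSign.ACTIVATION),),
                annotations=pmid(),
            )
        )
        reactions.append(
            MapReaction(
                reaction_id=tsl_id,
                reaction_class=ReactionClass.TRANSLATION,
                reactants=(rna_id,),
                products=(prot_id,),
                annotations=pmid(),
            )
        )
        tail_nodes.update({gene_id, rna_id, prot_id, tsc_id, tsl_id})

    model = MapModel(
        species=species, reactions=reactions, name=f"synthetic_map_seed{spec.seed}"
    )
    model.validate()
    truth.tf_ids = tf_ids
    truth.tail_nodes = frozenset(tail_nodes)
    truth.n_species = len(species)
    truth.n_reactions = len(reactions)
    truth.n_arcs = sum(len(r.participant_ids()) for r in reactions)
    truth.n_proteins = len(
        {s.protein_reference for s in species if s.species_class is SpeciesClass.PROTEIN}
    )
    return model, truth


# ---------------------------------------------------------------------------
# interactome generator

#: methods stamped on generated records
_WHITELISTED = ("MI:0018", "MI:0397", "MI:0090")
_OFF_WHITELIST = ("MI:0004", "MI:0114", "MI:0401")
_METHOD_NAMES = {
    "MI:0018": "two hybrid",
    "MI:0397": "two hybrid array",
    "MI:0090": "protein complementation assay",
    "MI:0004": "affinity chromatography technology",
    "MI:0114": "x-ray crystallography",
    "MI:0401": "biochemical",
}


@dataclass
class PpiGroundTruth:
    planted: list[str]
    decoys: list[str]
    partners: dict[str, frozenset[str]] = field(default_factory=dict)
    n_records: int = 0
    n_offmethod_records: int = 0

    def as_dict(self) -> dict:
        return {
            "planted": list(self.planted),
            "decoys": list(self.decoys),
            "partners": {k: sorted(v) for k, v in self.partners.items()},
            "n_records": self.n_records,
            "n_offmethod_records": self.n_offmethod_records,
        }


def _mitab_line(a: str, b: str, method: str, rng: random.Random) -> str:
    mname = _METHOD_NAMES[method]
    return "\t".join(
        [
            f"uniprotkb:{a}",
            f"uniprotkb:{b}",
            "-",
            "-",
            f"uniprotkb:{a}(gene name)",
            f"uniprotkb:{b}(gene name)",
            f'psi-mi:"{method}"({mname})',
            "-",
            f"pubmed:{rng.randint(1000000, 9999999)}",
            "taxid:9606(human)",
            "taxid:9606(human)",
            'psi-mi:"MI:0407"(direct interaction)',
            'psi-mi:"MI:0469"(intact)',
            f"intact:EBI-{rng.randint(100000, 999999)}",
            "-",
        ]
    )


def generate_interactome(
    model: MapModel,
    spec: GeneratorSpec,
    path: str | Path,
) -> tuple[Path, PpiGroundTruth]:
    """Write a PSI-MITAB 2.5 file of planted tight candidates plus decoys.

    Planted candidates connect to ``ceil(planted_wiring_fraction x
    |map proteins|)`` uniformly chosen map proteins with whitelisted
    detection methods; decoys get 1-2 partners, and a stated fraction of
    decoy records carries a non-whitelisted method so the binary-physical
    filter has something to reject.
    """
    from .model import unique_protein_set
    from .ppi import protein_projection

    rng = random.Random(spec.seed + 7919)
    map_proteins = sorted(unique_protein_set(model))
    if not map_proteins:
        raise ValueError("model has no map proteins to wire an interactome to")
    truth = PpiGroundTruth(planted=[], decoys=[])
    lines: list[str] = []

    # a tight interactor closes triangles with the map by definition, so a
    # planted partner set must contain at least one pair of map-adjacent
    # proteins; uniform draws are retried (then repaired) until they do
    projection = protein_projection(model)
    proj_edges = sorted(tuple(sorted(e)) for e in projection.edges)

    def has_adjacent_pair(partners: list[str]) -> bool:
        pset = set(partners)
        return any(u in pset and v in pset for u, v in proj_edges)

    k_planted = math.ceil(spec.planted_wiring_fraction * len(map_proteins))
    for i in range(spec.n_planted_candidates):
        sym = f"EXP{i}"
        truth.planted.append(sym)
        k = min(k_planted, len(map_proteins))
        partners = rng.sample(map_proteins, k=k)
        tries = 0
        while proj_edges and not has_adjacent_pair(partners) and tries < 50:
            partners = rng.sample(map_proteins, k=k)
            tries += 1
        if proj_edges and not has_adjacent_pair(partners) and k >= 2:
            u, v = rng.choice(proj_edges)
            partners = sorted((set(partners) - set(partners[:2])) | {u, v})
        truth.partners[sym] = frozenset(partners)
        for p in sorted(partners):
            lines.append(_mitab_line(sym, p, rng.choice(_WHITELISTED), rng))

    for i in range(spec.n_decoys):
        sym = f"DEC{i}"
        truth.decoys.append(sym)
        k = rng.randint(*spec.decoy_degree)
        partners = rng.sample(map_proteins, k=min(k, len(map_proteins)))
        truth.partners[sym] = frozenset(partners)
        for p in sorted(partners):
            if rng.random() < spec.decoy_offmethod_fraction:
                method = rng.choice(_OFF_WHITELIST)
                truth.n_offmethod_records += 1
            else:
                method = rng.choice(_WHITELISTED)
            lines.append(_mitab_line(sym, p, method, rng))

    truth.n_records = len(lines)
    path = Path(path)
    path.write_text("\n".join(lines) + ("\n" if lines else ""))
    return path, truth
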