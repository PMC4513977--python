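"""Typed in-memory representation of a process-description signaling map.

A map in SBGN process-description style has two kinds of first-class
entities: *species* (a molecule in a specific state, compartment and
complexation context) and *reactions* (the transformations between
them, possibly catalysed or inhibited by modifier species).  Several
species can be states of one underlying molecule; the shared
``protein_reference`` symbol ties them together and is what "unique
proteins" counts collapse onto.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Mapping


class SpeciesClass(str, Enum):
    PROTEIN = "PROTEIN"
    GENE = "GENE"
    RNA = "RNA"
    COMPLEX = "COMPLEX"
    SIMPLE_MOLECULE = "SIMPLE_MOLECULE"
    ION = "ION"
    DRUG = "DRUG"
    PHENOTYPE = "PHENOTYPE"
    DEGRADED = "DEGRADED"
    UNKNOWN = "UNKNOWN"


class ReactionClass(str, Enum):
    STATE_TRANSITION = "STATE_TRANSITION"
    HETERODIMER_ASSOCIATION = "HETERODIMER_ASSOCIATION"
    DISSOCIATION = "DISSOCIATION"
    TRANSPORT = "TRANSPORT"
    TRANSCRIPTION = "TRANSCRIPTION"
    TRANSLATION = "TRANSLATION"
    TRUNCATION = "TRUNCATION"
    KNOWN_TRANSITION_OMITTED = "KNOWN_TRANSITION_OMITTED"
    UNKNOWN_TRANSITION = "UNKNOWN_TRANSITION"
    UNKNOWN_NEGATIVE_INFLUENCE = "UNKNOWN_NEGATIVE_INFLUENCE"
    POSITIVE_INFLUENCE = "POSITIVE_INFLUENCE"


class ModifierSign(str, Enum):
    ACTIVATION = "ACTIVATION"
    INHIBITION = "INHIBITION"
    UNKNOWN = "UNKNOWN"


#: Species classes whose members carry a non-empty protein_reference.
_REFERENCED_CLASSES = {SpeciesClass.PROTEIN, SpeciesClass.RNA}

_PMID_RE = re.compile(r"PMID\D{0,3}(\d{6,9})", re.IGNORECASE)

#: state suffixes stripped when normalising a display name to a molecule symbol
_STATE_SUFFIX_RE = re.compile(
    r"[_\-\s]+(phosphorylated|phospho|active|inactive|ubiquitinated|cleaved|"
    r"gtp|gdp)$",
    re.IGNORECASE,
)


def extract_pmids(text: str) -> tuple[str, ...]:
    """Pull PubMed identifiers (6-9 digit tokens after 'PMID') out of free text."""
    if not text:
        return ()
    return tuple(dict.fromkeys(_PMID_RE.findall(text)))


def normalize_symbol(display_name: str) -> str:
    """Normalised molecule symbol: trimmed, state suffixes stripped, upper-cased."""
    sym = display_name.strip()
    while True:
        stripped = _STATE_SUFFIX_RE.sub("", sym)
        if stripped == sym or not stripped:
            break
        sym = stripped
    return sym.upper()


@dataclass(frozen=True)
class MapSpecies:
    species_id: str
    display_name: str
    species_class: SpeciesClass = SpeciesClass.UNKNOWN
    protein_reference: str = ""
    compartment: str = "default"
    state_tags: frozenset[str] = frozenset()
    complex_members: tuple[str, ...] = ()
    annotations: tuple[str, ...] = ()  # PMIDs / cell-line names from notes


@dataclass(frozen=True)
class MapReaction:
    reaction_id: str
    reaction_class: ReactionClass = ReactionClass.STATE_TRANSITION
    reactants: tuple[str, ...] = ()
    products: tuple[str, ...] = ()
    modifiers: tuple[tuple[str, ModifierSign], ...] = ()
    annotations: tuple[str, ...] = ()

    def participant_ids(self) -> tuple[str, ...]:
        return self.reactants + self.products + tuple(m for m, _ in self.modifiers)


class ModelIntegrityError(ValueError):
    """A reaction references a species absent from the model."""


@dataclass
class MapModel:
    species: list[MapSpecies] = field(default_factory=list)
    reactions: list[MapReaction] = field(default_factory=list)
    name: str = "map"
    source: str = ""
    sbml_level: int = 2
    sbml_version: int = 4

    def species_by_id(self) -> dict[str, MapSpecies]:
        return {s.species_id: s for s in self.species}

    def validate(self) -> None:
        ids = [s.species_id for s in self.species]
        if len(ids) != len(set(ids)):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ModelIntegrityError(f"duplicate species ids: {dup}")
        known = set(ids)
        for r in self.reactions:
            if not (r.reactants or r.products):
                raise ModelIntegrityError(
                    f"reaction {r.reaction_id} has no reactants or products"
                )
            missing = [p for p in r.participant_ids() if p not in known]
            if missing:
                raise ModelIntegrityError(
                    f"reaction {r.reaction_id} references unknown species {missing}"
                )

    def sorted_copy(self) -> "MapModel":
        """Canonical ordering by identifier; used by the byte-stable writers."""
        return replace(
            self,
            species=sorted(self.species, key=lambda s: s.species_id),
            reactions=sorted(self.reactions, key=lambda r: r.reaction_id),
        )


# ---------------------------------------------------------------------------
# category accounting

#: higher-level species rows of the standard map-overview table
SPECIES_GROUPS: Mapping[str, tuple[SpeciesClass, ...]] = {
    "Proteins": (SpeciesClass.PROTEIN,),
    "Complexes": (SpeciesClass.COMPLEX,),
    "Genes": (SpeciesClass.GENE,),
    "RNAs": (SpeciesClass.RNA,),
    "Other": (
        SpeciesClass.SIMPLE_MOLECULE,
        SpeciesClass.PHENOTYPE,
        SpeciesClass.DEGRADED,
        SpeciesClass.ION,
        SpeciesClass.DRUG,
        SpeciesClass.UNKNOWN,
    ),
}

REACTION_GROUPS: Mapping[str, tuple[ReactionClass, ...]] = {
    "Heterodimer associations and dissociations": (
        ReactionClass.HETERODIMER_ASSOCIATION,
        ReactionClass.DISSOCIATION,
    ),
    "State transitions": (ReactionClass.STATE_TRANSITION,),
    "Transports": (ReactionClass.TRANSPORT,),
    "Transcriptions and translations": (
        ReactionClass.TRANSCRIPTION,
        ReactionClass.TRANSLATION,
    ),
    "Other": (
        ReactionClass.KNOWN_TRANSITION_OMITTED,
        ReactionClass.TRUNCATION,
        ReactionClass.UNKNOWN_TRANSITION,
        ReactionClass.UNKNOWN_NEGATIVE_INFLUENCE,
        ReactionClass.POSITIVE_INFLUENCE,
    ),
}


def summarize_categories(model: MapModel) -> dict:
    """Map-overview accounting: species and reactions per category.

    Returns a dict with raw per-class counts, grouped table rows, totals and
    the unique-molecule counts (proteins, RNAs).  Rows always sum to the
    totals; an empty model yields an all-zero table.
    """
    species_counts = {c.value: 0 for c in SpeciesClass}
    for s in model.species:
        species_counts[s.species_class.value] += 1
    reaction_counts = {c.value: 0 for c in ReactionClass}
    for r in model.reactions:
        reaction_counts[r.reaction_class.value] += 1

    species_rows = {
        row: sum(species_counts[c.value] for c in classes)
        for row, classes in SPECIES_GROUPS.items()
    }
    reaction_rows = {
        row: sum(reaction_counts[c.value] for c in classes)
        for row, classes in REACTION_GROUPS.items()
    }
    unique_rnas = {
        s.protein_reference
        for s in model.species
        if s.species_class is SpeciesClass.RNA and s.protein_reference
    }
    return {
        "n_species": len(model.species),
        "n_reactions": len(model.reactions),
        "species_by_class": species_counts,
        "reactions_by_class": reaction_counts,
        "species_rows": species_rows,
        "reaction_rows": reaction_rows,
        "unique_proteins": len(unique_protein_set(model)),
        "unique_rnas": len(unique_rnas),
    }


def unique_protein_set(
    model: MapModel, include_degraded: bool = False
) -> frozenset[str]:
    """Distinct molecule symbols over protein species and complex members.

    All states/compartment copies of one molecule share a
    ``protein_reference`` and collapse to a single symbol.  Degraded
    products are excluded by default.
    """
    symbols: set[str] = set()
    for s in model.species:
        if s.species_class is SpeciesClass.DEGRADED and not include_degraded:
            continue
        if s.species_class is SpeciesClass.PROTEIN and s.protein_reference:
            symbols.add(s.protein_reference)
        elif s.species_class is SpeciesClass.COMPLEX:
            symbols.update(m for m in s.complex_members if m)
    return frozenset(symbols)


def _iter_protein_symbols(species: Iterable[MapSpecies]) -> Iterable[str]:
    for s in species:
        if s.protein_reference:
            yield s.protein_reference
        yield from s.complex_members
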