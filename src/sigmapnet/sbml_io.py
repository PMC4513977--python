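"""Reading and writing CellDesigner-dialect SBML signaling maps.

Only the subset of SBML Level 2 + the CellDesigner extension that carries
network semantics is modeled: species with a CellDesigner class, a protein
reference shared by all states of one molecule, state tags, complex
membership, reaction classes, signed modifier arcs, and PMID annotations in
the notes.  Layout, kinetics and rendering information are ignored on read
and never written.

When the CellDesigner extension is absent (plain SBML), species classes may
be supplied through ``class_overrides``; everything else degrades to
UNKNOWN rather than failing, so the pipeline also runs on generic models.
"""

from __future__ import annotations

import logging
import xml.etree.ElementTree as ET
from pathlib import Path
from typing import Mapping

import networkx as nx

from .model import (
    MapModel,
    MapReaction,
    MapSpecies,
    ModifierSign,
    ReactionClass,
    SpeciesClass,
    extract_pmids,
    normalize_symbol,
)

logger = logging.getLogger(__name__)

SBML_NS = "http://www.sbml.org/sbml/level2/version4"
CD_NS = "http://www.sbml.org/2001/ns/celldesigner"

# CellDesigner modification types -> modifier sign
_MODIFICATION_SIGN = {
    "CATALYSIS": ModifierSign.ACTIVATION,
    "UNKNOWN_CATALYSIS": ModifierSign.ACTIVATION,
    "PHYSICAL_STIMULATION": ModifierSign.ACTIVATION,
    "TRIGGER": ModifierSign.ACTIVATION,
    "TRANSCRIPTIONAL_ACTIVATION": ModifierSign.ACTIVATION,
    "TRANSLATIONAL_ACTIVATION": ModifierSign.ACTIVATION,
    "INHIBITION": ModifierSign.INHIBITION,
    "UNKNOWN_INHIBITION": ModifierSign.INHIBITION,
    "TRANSCRIPTIONAL_INHIBITION": ModifierSign.INHIBITION,
    "TRANSLATIONAL_INHIBITION": ModifierSign.INHIBITION,
}
_SIGN_MODIFICATION = {
    ModifierSign.ACTIVATION: "CATALYSIS",
    ModifierSign.INHIBITION: "INHIBITION",
    ModifierSign.UNKNOWN: "MODULATION",
}


class SbmlParseError(ValueError):
    pass


class EmptyModelError(SbmlParseError):
    pass


def _local(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def _find_all(elem: ET.Element, local_name: str) -> list[ET.Element]:
    return [e for e in elem.iter() if _local(e.tag) == local_name]


def _notes_annotations(elem: ET.Element) -> tuple[str, ...]:
    notes = next(iter(_find_all(elem, "notes")), None)
    if notes is None:
        return ()
    text = " ".join(t.strip() for t in notes.itertext() if t.strip())
    ann: list[str] = ["PMID:" + p for p in extract_pmids(text)]
    for chunk in text.split(";"):
        chunk = chunk.strip()
        low = chunk.lower()
        if low.startswith("cell line:"):
            ann.append(chunk[len("cell line:") :].strip())
    return tuple(dict.fromkeys(ann))


def parse_celldesigner_sbml(
    path: str | Path,
    class_overrides: Mapping[str, str | SpeciesClass] | None = None,
) -> MapModel:
    """Parse a CellDesigner-dialect SBML file into a :class:`MapModel`.

    ``class_overrides`` maps species ids to classes for files lacking the
    CellDesigner extension.  Unknown class strings are recorded as UNKNOWN
    with a logged warning, never an error.
    """
    path = Path(path)
    try:
        tree = ET.parse(path)
    except ET.ParseError as exc:
        raise SbmlParseError(
            f"{path}: malformed XML at line {exc.position[0]}: {exc.msg}"
        ) from exc
    root = tree.getroot()
    if _local(root.tag) != "sbml":
        raise SbmlParseError(f"{path}: root element is not <sbml>")
    model_el = next(iter(_find_all(root, "model")), None)
    if model_el is None:
        raise SbmlParseError(f"{path}: no <model> element")

    overrides = {
        k: SpeciesClass(v) if not isinstance(v, SpeciesClass) else v
        for k, v in (class_overrides or {}).items()
    }

    # CellDesigner protein reference table: protein id -> symbol
    protein_names: dict[str, str] = {}
    for prot in _find_all(model_el, "protein"):
        pid, name = prot.get("id"), prot.get("name")
        if pid and name:
            protein_names[pid] = normalize_symbol(name)

    def identity(elem: ET.Element) -> tuple[SpeciesClass | None, str, frozenset[str]]:
        """CellDesigner class, protein symbol and state tags of one species."""
        cls: SpeciesClass | None = None
        ref = ""
        tags: set[str] = set()
        for ident in _find_all(elem, "speciesIdentity"):
            for child in ident.iter():
                name = _local(child.tag)
                if name == "class" and child.text:
                    raw = child.text.strip().upper()
                    try:
                        cls = SpeciesClass(raw)
                    except ValueError:
                        logger.warning("unknown CellDesigner class %r -> UNKNOWN", raw)
                        cls = SpeciesClass.UNKNOWN
                elif name == "proteinReference" and child.text:
                    key = child.text.strip()
                    ref = protein_names.get(key, normalize_symbol(key))
                elif name == "modification":
                    state = child.get("state")
                    if state:
                        tags.add(state)
                elif name == "structuralState":
                    state = child.get("structuralState")
                    if state:
                        tags.add(state)
        return cls, ref, frozenset(tags)

    # included species: members living inside complexes
    complex_members: dict[str, list[str]] = {}
    for inc in _find_all(model_el, "listOfIncludedSpecies"):
        for sp in _find_all(inc, "species"):
            parent = None
            for ann in _find_all(sp, "complexSpecies"):
                if ann.text:
                    parent = ann.text.strip()
            parent = sp.get("complexSpecies") or parent
            cls, ref, _ = identity(sp)
            symbol = ref or normalize_symbol(sp.get("name") or sp.get("id") or "")
            if parent and symbol and cls in (None, SpeciesClass.PROTEIN):
                complex_members.setdefault(parent, []).append(symbol)

    species: list[MapSpecies] = []
    top_species: list[ET.Element] = []
    for lst in model_el:
        if _local(lst.tag) == "listOfSpecies":
            top_species = [e for e in lst if _local(e.tag) == "species"]
    for sp in top_species:
        sid = sp.get("id") or ""
        name = sp.get("name") or sid
        cls, ref, tags = identity(sp)
        if cls is None:
            cls = overrides.get(sid, SpeciesClass.UNKNOWN)
        if cls is SpeciesClass.PROTEIN and not ref:
            ref = normalize_symbol(name)
        if cls is SpeciesClass.RNA and not ref:
            ref = normalize_symbol(name)
        species.append(
            MapSpecies(
                species_id=sid,
                display_name=name,
                species_class=cls,
                protein_reference=ref if cls in (SpeciesClass.PROTEIN, SpeciesClass.RNA) else "",
                compartment=sp.get("compartment") or "default",
                state_tags=tags,
                complex_members=tuple(sorted(complex_members.get(sid, ()))),
                annotations=_notes_annotations(sp),
            )
        )
    if not species:
        raise EmptyModelError(f"{path}: SBML model contains no species")

    reactions: list[MapReaction] = []
    for lst in model_el:
        if _local(lst.tag) != "listOfReactions":
            continue
        for rx in lst:
            if _local(rx.tag) != "reaction":
                continue
            rid = rx.get("id") or ""
            rclass = ReactionClass.STATE_TRANSITION
            for rt in _find_all(rx, "reactionType"):
                if rt.text:
                    raw = rt.text.strip().upper()
                    try:
                        rclass = ReactionClass(raw)
                    except ValueError:
                        logger.warning("unknown reaction type %r -> UNKNOWN_TRANSITION", raw)
                        rclass = ReactionClass.UNKNOWN_TRANSITION
            reactants: list[str] = []
            products: list[str] = []
            modifier_ids: list[str] = []
            for sub in rx:
                ln = _local(sub.tag)
                refs = [
                    e.get("species")
                    for e in sub
                    if _local(e.tag).endswith("SpeciesReference")
                    or _local(e.tag) == "speciesReference"
                ]
                refs = [r for r in refs if r]
                if ln == "listOfReactants":
                    reactants.extend(refs)
                elif ln == "listOfProducts":
                    products.extend(refs)
                elif ln == "listOfModifiers":
                    modifier_ids.extend(refs)
            mod_signs: dict[str, ModifierSign] = {}
            for mod in _find_all(rx, "modification"):
                mtype = (mod.get("type") or "").upper()
                targets = (mod.get("modifiers") or mod.get("aliases") or "").split(",")
                sign = _MODIFICATION_SIGN.get(mtype, ModifierSign.UNKNOWN)
                for t in targets:
                    t = t.strip()
                    if t:
                        mod_signs[t] = sign
            modifiers = tuple(
                (m, mod_signs.get(m, ModifierSign.UNKNOWN)) for m in modifier_ids
            )
            reactions.append(
                MapReaction(
                    reaction_id=rid,
                    reaction_class=rclass,
                    reactants=tuple(reactants),
                    products=tuple(products),
                    modifiers=modifiers,
                    annotations=_notes_annotations(rx),
                )
            )

    model = MapModel(
        species=species,
        reactions=reactions,
        name=model_el.get("name") or model_el.get("id") or path.stem,
        source=str(path),
    )
    model.validate()
    return model


# ---------------------------------------------------------------------------
# writers


def _sub(parent: ET.Element, tag: str, **attrs: str) -> ET.Element:
    return ET.SubElement(parent, tag, {k: v for k, v in attrs.items() if v})


def write_sbml(model: MapModel, path: str | Path) -> Path:
    """Serialise a model as SBML L2 with the CellDesigner extension subset.

    Output is byte-stable for a given model: species, reactions and every
    annotation list are written in sorted identifier order.
    """
    model = model.sorted_copy()
    model.validate()
    ET.register_namespace("", SBML_NS)
    ET.register_namespace("celldesigner", CD_NS)
    root = ET.Element(f"{{{SBML_NS}}}sbml", {"level": "2", "version": "4"})
    model_el = _sub(root, f"{{{SBML_NS}}}model", id=_xml_id(model.name), name=model.name)

    # model-level extension: protein reference table
    symbols = sorted(
        {s.protein_reference for s in model.species if s.protein_reference}
        | {m for s in model.species for m in s.complex_members}
    )
    ann = _sub(model_el, f"{{{SBML_NS}}}annotation")
    ext = _sub(ann, f"{{{CD_NS}}}extension")
    prot_list = _sub(ext, f"{{{CD_NS}}}listOfProteins")
    prot_id = {sym: f"pr_{i}" for i, sym in enumerate(symbols)}
    for sym in symbols:
        _sub(prot_list, f"{{{CD_NS}}}protein", id=prot_id[sym], name=sym, type="GENERIC")

    compartments = sorted({s.compartment for s in model.species} or {"default"})
    comp_list = _sub(model_el, f"{{{SBML_NS}}}listOfCompartments")
    for c in compartments:
        _sub(comp_list, f"{{{SBML_NS}}}compartment", id=_xml_id(c), size="1")

    sp_list = _sub(model_el, f"{{{SBML_NS}}}listOfSpecies")
    included: list[tuple[str, str]] = []  # (complex id, member symbol)
    for s in model.species:
        el = _sub(
            sp_list,
            f"{{{SBML_NS}}}species",
            id=s.species_id,
            name=s.display_name,
            compartment=_xml_id(s.compartment),
        )
        _write_notes(el, s.annotations)
        s_ann = _sub(el, f"{{{SBML_NS}}}annotation")
        s_ext = _sub(s_ann, f"{{{CD_NS}}}extension")
        ident = _sub(s_ext, f"{{{CD_NS}}}speciesIdentity")
        cls = _sub(ident, f"{{{CD_NS}}}class")
        cls.text = s.species_class.value
        if s.protein_reference:
            ref = _sub(ident, f"{{{CD_NS}}}proteinReference")
            ref.text = prot_id.get(s.protein_reference, s.protein_reference)
        if s.state_tags:
            state = _sub(ident, f"{{{CD_NS}}}state")
            mods = _sub(state, f"{{{CD_NS}}}listOfModifications")
            for i, tag in enumerate(sorted(s.state_tags)):
                _sub(mods, f"{{{CD_NS}}}modification", residue=str(i), state=tag)
        for member in s.complex_members:
            included.append((s.species_id, member))

    if included:
        inc_list = _sub(ext, f"{{{CD_NS}}}listOfIncludedSpecies")
        for i, (cid, member) in enumerate(sorted(included)):
            isp = _sub(
                inc_list,
                f"{{{CD_NS}}}species",
                id=f"inc_{i}",
                name=member,
                complexSpecies=cid,
            )
            ident = _sub(isp, f"{{{CD_NS}}}speciesIdentity")
            c = _sub(ident, f"{{{CD_NS}}}class")
            c.text = SpeciesClass.PROTEIN.value
            ref = _sub(ident, f"{{{CD_NS}}}proteinReference")
            ref.text = prot_id.get(member, member)

    rx_list = _sub(model_el, f"{{{SBML_NS}}}listOfReactions")
    for r in model.reactions:
        el = _sub(rx_list, f"{{{SBML_NS}}}reaction", id=r.reaction_id, reversible="false")
        _write_notes(el, r.annotations)
        r_ann = _sub(el, f"{{{SBML_NS}}}annotation")
        r_ext = _sub(r_ann, f"{{{CD_NS}}}extension")
        rt = _sub(r_ext, f"{{{CD_NS}}}reactionType")
        rt.text = r.reaction_class.value
        if r.modifiers:
            mods = _sub(r_ext, f"{{{CD_NS}}}listOfModification")
            for sid, sign in r.modifiers:
                _sub(
                    mods,
                    f"{{{CD_NS}}}modification",
                    type=_SIGN_MODIFICATION[sign],
                    modifiers=sid,
                )
        if r.reactants:
            lst = _sub(el, f"{{{SBML_NS}}}listOfReactants")
            for sid in r.reactants:
                _sub(lst, f"{{{SBML_NS}}}speciesReference", species=sid)
        if r.products:
            lst = _sub(el, f"{{{SBML_NS}}}listOfProducts")
            for sid in r.products:
                _sub(lst, f"{{{SBML_NS}}}speciesReference", species=sid)
        if r.modifiers:
            lst = _sub(el, f"{{{SBML_NS}}}listOfModifiers")
            for sid, _ in r.modifiers:
                _sub(lst, f"{{{SBML_NS}}}modifierSpeciesReference", species=sid)

    ET.indent(root)
    path = Path(path)
    path.write_bytes(ET.tostring(root, encoding="utf-8", xml_declaration=True))
    return path


def _write_notes(el: ET.Element, annotations: tuple[str, ...]) -> None:
    if not annotations:
        return
    notes = _sub(el, f"{{{SBML_NS}}}notes")
    body = ET.SubElement(notes, "{http://www.w3.org/1999/xhtml}body")
    parts = []
    for a in annotations:
        parts.append(a if a.upper().startswith("PMID") else f"Cell line: {a}")
    body.text = "; ".join(parts)


def _xml_id(text: str) -> str:
    out = "".join(c if c.isalnum() or c == "_" else "_" for c in text)
    return out if out and not out[0].isdigit() else "_" + out


def write_sif(graph: nx.DiGraph, path: str | Path) -> Path:
    """Tab-separated ``source relation target`` lines, sorted for stability."""
    lines = []
    for u, v, data in graph.edges(data=True):
        rel = data.get("relation") or "|".join(sorted(data.get("roles", ("edge",))))
        lines.append(f"{u}\t{rel.lower()}\t{v}")
    Path(path).write_text("\n".join(sorted(lines)) + ("\n" if lines else ""))
    return Path(path)


def write_graphml(graph: nx.DiGraph, path: str | Path) -> Path:
    """GraphML export with attributes flattened to strings (byte-stable)."""
    out = nx.DiGraph()
    for n in sorted(graph.nodes):
        out.add_node(n, **{k: str(v) for k, v in graph.nodes[n].items()})
    for u, v in sorted(graph.edges):
        out.add_edge(u, v, **{
            k: "|".join(sorted(val)) if isinstance(val, (set, frozenset, tuple)) else str(val)
            for k, val in graph.edges[u, v].items()
        })
    nx.write_graphml(out, path)
    return Path(path)
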