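"""End-to-end pipeline: parse -> prune -> topology -> decompose -> expand.

`run_pipeline` orchestrates the stages on declared inputs and writes a
plain-file report bundle; `compare_to_reference` checks a bundle against a
reference-counts file.  Outputs contain no timestamps, so two runs on
identical inputs produce byte-identical bundles.
"""

from __future__ import annotations

import hashlib
import json
import shutil
from pathlib import Path

import pandas as pd
from pydantic import BaseModel, Field

from . import __version__
from .decompose import decompose
from .graph import build_reaction_graph, prune_tf_downstream, topology_summary
from .model import summarize_categories, unique_protein_set
from .ppi import (
    DEFAULT_METHOD_WHITELIST,
    base_expansion_network,
    filter_binary_physical,
    pathexpand_select,
    read_psi_mitab,
)
from .sbml_io import parse_celldesigner_sbml, write_sif


class PipelineConfig(BaseModel):
    """Declarative configuration; defaults are the standard thresholds
    (hubs at degree > 5, sub-network merging at >= 50 % overlap)."""

    sbml_path: Path
    mitab_path: Path | None = None
    tf_list_path: Path | None = None
    whitelist_path: Path | None = None
    alias_path: Path | None = None
    hub_threshold: int = Field(default=5, ge=0)
    overlap_threshold: float = Field(default=0.5, gt=0.0, le=1.0)
    overlap_measure: str = "overlap"
    criteria: str = "all"
    out_dir: Path = Path("sigmapnet_out")
    seed: int = 0


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def _read_lines(path: Path) -> list[str]:
    return [
        ln.strip()
        for ln in Path(path).read_text().splitlines()
        if ln.strip() and not ln.startswith("#")
    ]


def _sha256(path: Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> Path:
    """Run every stage and write the report bundle to ``config.out_dir``.

    Bundle contents: ``summary.json`` (map-overview accounting),
    ``topology.tsv``, ``modules.tsv`` + ``modules/`` per-module node lists,
    ``modular_map.sif``, ``expansion.tsv`` (when a MITAB file is
    configured) and ``manifest.json``.  Any stage error removes partial
    outputs and raises :class:`StageError` naming the stage.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    try:
        return _run_stages(config, out)
    except StageError:
        shutil.rmtree(out, ignore_errors=True)
        raise


def _run_stages(config: PipelineConfig, out: Path) -> Path:
    artifacts: dict[str, str] = {}

    # --- sbml_map_io -------------------------------------------------------
    try:
        model = parse_celldesigner_sbml(config.sbml_path)
        summary = summarize_categories(model)
        map_proteins = set(unique_protein_set(model))
        (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
        artifacts["summary"] = "summary.json"
    except Exception as exc:  # noqa: BLE001 - stage boundary
        raise StageError("sbml_map_io", exc) from exc

    # --- reaction_graph ----------------------------------------------------
    try:
        graph = build_reaction_graph(model)
        tf_ids = set(_read_lines(config.tf_list_path)) if config.tf_list_path else set()
        pruned = prune_tf_downstream(graph, tf_ids)
        topo = topology_summary(pruned, hub_threshold=config.hub_threshold)
        topo_df = pd.DataFrame(
            topo.to_rows(),
            columns=["node_id", "kind", "degree", "closeness", "is_hub"],
        )
        topo_df.to_csv(out / "topology.tsv", sep="\t", index=False, float_format="%.6g")
        artifacts["topology"] = "topology.tsv"
    except Exception as exc:
        raise StageError("reaction_graph", exc) from exc

    # --- decomposition -----------------------------------------------------
    try:
        modules, modmap, report = decompose(
            pruned,
            model,
            overlap_threshold=config.overlap_threshold,
            measure=config.overlap_measure,
        )
        rows = []
        for m in modules:
            for role, nodes in (
                ("defining", m.defining),
                ("incoming", m.incoming),
                ("outgoing", m.outgoing),
            ):
                for n in sorted(nodes):
                    rows.append((m.name, role, n, pruned.nodes[n].get("kind", "")))
        pd.DataFrame(rows, columns=["module", "role", "node_id", "kind"]).to_csv(
            out / "modules.tsv", sep="\t", index=False
        )
        bundle_dir = out / "modules"
        bundle_dir.mkdir(exist_ok=True)
        for m in modules:
            (bundle_dir / f"{_safe(m.name)}.txt").write_text(
                "\n".join(sorted(m.defining)) + "\n"
            )
        sif_lines = sorted(
            f"{a}\t{'activates' if s == 'ACTIVATION' else 'inhibits'}\t{b}"
            for a, b, s in modmap.inter_module_edges
        )
        (out / "modular_map.sif").write_text(
            "\n".join(sif_lines) + ("\n" if sif_lines else "")
        )
        write_sif(pruned, out / "bipartite_graph.sif")
        completeness = {
            "missing_nodes": sorted(report.missing_nodes),
            "missing_edges": sorted(map(list, report.missing_edges)),
            "complete": report.complete,
        }
        (out / "completeness.json").write_text(json.dumps(completeness, indent=2))
        artifacts["modules"] = "modules.tsv"
        artifacts["modular_map"] = "modular_map.sif"
    except Exception as exc:
        raise StageError("decomposition", exc) from exc

    # --- ppi_integration ---------------------------------------------------
    if config.mitab_path is not None:
        try:
            aliases = None
            if config.alias_path:
                aliases = dict(
                    ln.split("\t")[:2] for ln in _read_lines(config.alias_path)
                )
            whitelist = (
                set(_read_lines(config.whitelist_path))
                if config.whitelist_path
                else set(DEFAULT_METHOD_WHITELIST)
            )
            records, skip = read_psi_mitab(config.mitab_path, aliases=aliases)
            interactome = filter_binary_physical(records, whitelist)
            base = base_expansion_network(model, interactome)
            accepted, novel = pathexpand_select(
                base, interactome, map_proteins, criteria=config.criteria
            )
            seen = {r.candidate for r in accepted}
            exp_rows = [
                (
                    r.candidate,
                    r.n_map_partners,
                    round(r.delta_degree, 6),
                    round(r.delta_betweenness, 6),
                    round(r.delta_clustering, 6),
                    round(r.delta_path_length, 6),
                    r.accepted,
                    r.in_original_map,
                )
                for r in accepted
            ]
            pd.DataFrame(
                exp_rows,
                columns=[
                    "candidate",
                    "n_map_partners",
                    "delta_degree",
                    "delta_betweenness",
                    "delta_clustering",
                    "delta_path_length",
                    "accepted",
                    "in_original_map",
                ],
            ).to_csv(out / "expansion.tsv", sep="\t", index=False)
            artifacts["expansion"] = "expansion.tsv"
            artifacts["expansion_skipped_records"] = str(len(skip.skipped))
        except Exception as exc:
            raise StageError("ppi_integration", exc) from exc

    # --- manifest ----------------------------------------------------------
    inputs = {
        str(p): _sha256(p)
        for p in [
            config.sbml_path,
            config.mitab_path,
            config.tf_list_path,
            config.whitelist_path,
            config.alias_path,
        ]
        if p is not None and Path(p).exists()
    }
    manifest = {
        "version": __version__,
        "config": json.loads(config.model_dump_json()),
        "input_checksums": inputs,
        "artifacts": artifacts,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return out


def _safe(name: str) -> str:
    return "".join(c if c.isalnum() or c in "._-" else "_" for c in name)


def compare_to_reference(bundle_dir: str | Path, reference_path: str | Path) -> pd.DataFrame:
    """Check a bundle against a JSON file of reference counts.

    The reference maps target names to expected numbers; supported names:
    ``n_species``, ``n_reactions``, ``unique_proteins``, ``unique_rnas``,
    any species/reaction row of the overview table (e.g. ``Proteins``,
    ``State transitions``), ``pruned_nodes``, ``pruned_edges``,
    ``pruned_species``, ``pruned_reactions``, ``n_modules``.  Returns a
    pass/fail table with one row per target.
    """
    bundle = Path(bundle_dir)
    try:
        reference = json.loads(Path(reference_path).read_text())
        if not isinstance(reference, dict):
            raise ValueError("reference file must hold a JSON object")
    except json.JSONDecodeError as exc:
        raise ValueError(f"malformed reference file {reference_path}: {exc}") from exc

    summary = json.loads((bundle / "summary.json").read_text())
    topo = pd.read_csv(bundle / "topology.tsv", sep="\t")
    modules = pd.read_csv(bundle / "modules.tsv", sep="\t")
    observed: dict[str, float] = {
        "n_species": summary["n_species"],
        "n_reactions": summary["n_reactions"],
        "unique_proteins": summary["unique_proteins"],
        "unique_rnas": summary["unique_rnas"],
        **summary["species_rows"],
        **{k: v for k, v in summary["reaction_rows"].items() if k not in summary["species_rows"]},
        "pruned_nodes": len(topo),
        "pruned_species": int((topo["kind"] == "SPECIES").sum()),
        "pruned_reactions": int((topo["kind"] == "REACTION").sum()),
        "pruned_edges": int(topo["degree"].sum() // 2),
        "n_modules": modules["module"].nunique() if len(modules) else 0,
    }
    rows = []
    for key, expected in reference.items():
        got = observed.get(key)
        rows.append(
            (key, expected, got, got is not None and float(got) == float(expected))
        )
    return pd.DataFrame(rows, columns=["target", "expected", "observed", "passed"])
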