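"""End-to-end orchestration: build -> partition -> score -> intersect ->
modules -> enrich -> classify -> topology, for the overall network and
each compartment subnetwork.

A single YAML config drives the run; every method parameter (sampling
rounds 10000, reporter threshold 0.05, MCODE degree cutoff 2 and k-core
2, enrichment FDR 0.05, median aggregation) surfaces as a named key with
that default. The manifest records the config snapshot, derived seeds,
per-network counts, and SHA-256 checksums of all inputs and outputs, and
is byte-identical across reruns with the same config and inputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from . import enrichment as enr
from . import io as eio
from . import localization as loc
from . import mcode
from . import reporter as rep
from . import topology as topo
from .network import (
    DEFAULT_CURRENCY_COMPOUNDS,
    EnzymeNetwork,
    build_enzyme_network,
    undirected_view,
    write_edgelist,
)

__all__ = ["PipelineError", "RunManifest", "default_config", "run_pipeline"]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and offending input."""

    def __init__(self, stage: str, detail: str):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {detail}")


@dataclass
class RunManifest:
    config: dict[str, Any]
    seed: int
    derived_seeds: dict[str, int] = field(default_factory=dict)
    networks: dict[str, dict[str, Any]] = field(default_factory=dict)
    input_checksums: dict[str, str] = field(default_factory=dict)
    output_files: dict[str, str] = field(default_factory=dict)
    tally: list[dict[str, Any]] = field(default_factory=list)
    failed_stage: str | None = None

    def write(self, path: str | Path) -> None:
        record = {
            "config": self.config,
            "seed": self.seed,
            "derived_seeds": self.derived_seeds,
            "networks": self.networks,
            "input_checksums": self.input_checksums,
            "output_files": self.output_files,
            "tally": self.tally,
        }
        if self.failed_stage:
            record["FAILED"] = self.failed_stage
        Path(path).write_text(json.dumps(record, indent=2, sort_keys=True) + "\n")


def default_config() -> dict[str, Any]:
    return {
        "seed": 0,
        "rounds": 10000,
        "alpha": 0.05,
        "aggregation": "median",
        "null_pool": "gene",
        "gene_test": "welch_t",
        "mcode": {
            "degree_cutoff": 2,
            "vwp": 0.2,
            "k_core_min": 2,
            "haircut": True,
            "fluff": False,
            "fluff_density": 0.2,
        },
        "min_reporters": 1,
        "fdr_alpha": 0.05,
        "function_classes": None,
        "exclude_evidence_codes": [],
        "currency_compounds": sorted(DEFAULT_CURRENCY_COMPOUNDS),
        "inputs": {},
    }


def load_config(path: str | Path) -> dict[str, Any]:
    cfg = default_config()
    user = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
    for key, value in user.items():
        if key == "mcode" and isinstance(value, dict):
            cfg["mcode"].update(value)
        else:
            cfg[key] = value
    return cfg


def _sha256(path: Path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as handle:
        for chunk in iter(lambda: handle.read(1 << 16), b""):
            digest.update(chunk)
    return digest.hexdigest()


def _derive_seed(master: int, *tokens: str) -> int:
    material = ":".join([str(master), *tokens]).encode()
    return int.from_bytes(hashlib.sha256(material).digest()[:4], "big") % (2**31)


def _load_inputs(cfg: dict[str, Any]) -> dict[str, Any]:
    inputs = cfg["inputs"]
    try:
        reactions = eio.read_reactions(inputs["reactions"])
    except (KeyError, FileNotFoundError) as exc:
        raise PipelineError("read_reactions", str(exc)) from exc
    try:
        dag = eio.read_obo(inputs["ontology"])
        annotations = eio.read_gaf(inputs["annotations"])
        gene_map = eio.read_gene_enzyme_map(inputs["gene_map"])
    except (KeyError, FileNotFoundError, eio.FormatError) as exc:
        raise PipelineError("read_annotation_inputs", str(exc)) from exc

    pvalues: dict[str, dict[str, float]] = {}
    try:
        if "pvalues" in inputs:
            for cell_type, path in inputs["pvalues"].items():
                pvalues[cell_type] = eio.read_gene_pvalues(path)
        else:
            for cell_type, spec in inputs["expression"].items():
                ds = eio.read_expression(spec["matrix"], spec["groups"], cell_type)
                pvalues[cell_type] = eio.gene_pvalues_from_expression(
                    ds, method=cfg["gene_test"]
                )
    except (KeyError, FileNotFoundError, eio.FormatError, eio.ValidationError) as exc:
        raise PipelineError("gene_pvalues", str(exc)) from exc
    if len(pvalues) < 2:
        raise PipelineError("gene_pvalues", "need >=2 cell-type contrasts to intersect")
    return {
        "reactions": reactions,
        "dag": dag,
        "annotations": annotations,
        "gene_map": gene_map,
        "pvalues": pvalues,
    }


def _analyze_network(
    net: EnzymeNetwork,
    data: dict[str, Any],
    cfg: dict[str, Any],
    outdir: Path,
    manifest: RunManifest,
) -> None:
    """Score, intersect, detect modules, enrich and summarize one network."""
    key = net.compartment or "overall"
    gene_map: eio.GeneEnzymeMap = data["gene_map"]
    record: dict[str, Any] = {
        "nodes": net.graph.number_of_nodes(),
        "edges": net.graph.number_of_edges(),
    }
    manifest.networks[key] = record

    tables = []
    for cell_type, pvals in sorted(data["pvalues"].items()):
        pool = rep.null_pool_for_network(
            net, pvals, gene_map, strategy=cfg["null_pool"], mode=cfg["aggregation"]
        )
        if pool.size < 2:
            logger.warning("network %s: gene pool too small to score; skipped", key)
            record["reporters"] = 0
            record["modules"] = 0
            return
        seed = _derive_seed(cfg["seed"], "null", key, cell_type)
        manifest.derived_seeds[f"null:{key}:{cell_type}"] = seed
        null = rep.NullModel(
            pool=pool, rounds=cfg["rounds"], seed=seed, mode=cfg["aggregation"]
        )
        table = rep.score_network(net, pvals, gene_map, null, cell_type=cell_type)
        path = outdir / f"scores_{key}_{cell_type}.tsv"
        table.write(path, alpha=cfg["alpha"])
        manifest.output_files[path.name] = _sha256(path)
        tables.append(table)
        logger.info(
            "network %s / %s: scored %d enzymes, %d flagged",
            key, cell_type, len(table.table), len(table.flagged(cfg["alpha"])),
        )

    reporters = rep.intersect_reporters(tables, alpha=cfg["alpha"])
    record["reporters"] = len(reporters)
    (outdir / f"reporters_{key}.txt").write_text("\n".join(sorted(reporters)) + "\n")
    manifest.output_files[f"reporters_{key}.txt"] = _sha256(outdir / f"reporters_{key}.txt")

    und = undirected_view(net)
    if und.graph.number_of_nodes():
        summary = topo.summarize(und)
        tpath = outdir / f"topology_{key}.json"
        summary.to_json(tpath)
        manifest.output_files[tpath.name] = _sha256(tpath)
        if reporters and (set(und.graph.nodes) - reporters):
            cmp = topo.compare_reporter_topology(und, reporters & set(und.graph.nodes))
            record["reporter_degree_p"] = cmp.degree_p
            record["reporter_clustering_p"] = cmp.clustering_p

    mc = cfg["mcode"]
    modules = mcode.detect_modules(
        und,
        degree_cutoff=mc["degree_cutoff"],
        vwp=mc["vwp"],
        k_core_min=mc["k_core_min"],
        haircut=mc["haircut"],
        fluff=mc["fluff"],
        fluff_density=mc["fluff_density"],
    )
    reporter_modules = mcode.modules_with_reporters(
        modules, reporters, min_reporters=cfg["min_reporters"]
    )
    record["modules"] = len(reporter_modules)
    mpath = outdir / f"modules_{key}.tsv"
    mcode.write_modules(reporter_modules, mpath)
    manifest.output_files[mpath.name] = _sha256(mpath)

    # enrichment per reporter module against the network's gene universe
    scheme = enr.load_function_classes(cfg["function_classes"])
    universe = {g for e in net.enzymes for g in gene_map.genes_of(e)}
    term_to_genes: dict[str, set[str]] = {}
    names = {t: data["dag"].nodes[t].get("name", "") for t in data["dag"].nodes}
    for a in data["annotations"]:
        if a.aspect == "P" and a.object_id in universe:
            term_to_genes.setdefault(a.term_id, set()).add(a.object_id)
    per_class_totals = {label: 0 for label in enr.FUNCTION_CLASS_LABELS}
    for i, module in enumerate(reporter_modules, start=1):
        module_genes = {g for e in module.members for g in gene_map.genes_of(e)}
        results = enr.hypergeom_enrich(module_genes, term_to_genes, universe, names)
        results = enr.classify_terms(results, scheme)
        epath = outdir / f"enrichment_{key}_M{i}.tsv"
        enr.write_enrichment(results, epath)
        manifest.output_files[epath.name] = _sha256(epath)
        counts = enr.class_counts(results, fdr_alpha=cfg["fdr_alpha"])
        for label in enr.FUNCTION_CLASS_LABELS:
            per_class_totals[label] += counts[label]
        manifest.tally.append(
            {
                "network": key,
                "module": f"M{i}",
                "size": module.size,
                "reporters": sorted(module.reporters),
                **{f"n_{label}": counts[label] for label in enr.FUNCTION_CLASS_LABELS},
            }
        )
    record["class_counts"] = per_class_totals
    logger.info(
        "network %s: %d reporters, %d reporter modules, class counts %s",
        key, len(reporters), len(reporter_modules), per_class_totals,
    )


def run_pipeline(config: str | Path | dict[str, Any], outdir: str | Path | None = None) -> RunManifest:
    """Run all stages for the overall network and the six compartments.

    ``config`` is a YAML path or an already-merged config dict. Returns
    the manifest (also written to ``<outdir>/manifest.json``).
    """
    cfg = load_config(config) if not isinstance(config, dict) else {**default_config(), **config}
    outdir = Path(outdir or cfg.get("outdir", "results"))
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=_jsonable(cfg), seed=cfg["seed"])
    for name, path in sorted(_iter_input_paths(cfg["inputs"])):
        if Path(path).is_file():  # missing files fail in their own stage
            manifest.input_checksums[name] = _sha256(Path(path))

    try:
        data = _load_inputs(cfg)
        net = build_enzyme_network(
            data["reactions"], currency_compounds=frozenset(cfg["currency_compounds"])
        )
        epath = outdir / "network_overall.tsv"
        write_edgelist(net, epath)
        manifest.output_files[epath.name] = _sha256(epath)

        scheme = loc.CompartmentScheme()
        partition = loc.partition_enzymes(
            net,
            data["annotations"],
            data["gene_map"],
            data["dag"],
            scheme,
            exclude_evidence_codes=frozenset(cfg["exclude_evidence_codes"]),
        )
        ppath = outdir / "partition.tsv"
        loc.write_partition(partition, ppath)
        manifest.output_files[ppath.name] = _sha256(ppath)

        _analyze_network(net, data, cfg, outdir, manifest)
        for label in scheme.labels:
            sub = loc.compartment_subnetwork(net, partition, label, scheme)
            _analyze_network(sub, data, cfg, outdir, manifest)
    except PipelineError as exc:
        manifest.failed_stage = exc.stage
        manifest.write(outdir / "manifest.json")
        raise
    except Exception as exc:  # pragma: no cover - defensive
        manifest.failed_stage = type(exc).__name__
        manifest.write(outdir / "manifest.json")
        raise

    manifest.write(outdir / "manifest.json")
    return manifest


def _iter_input_paths(inputs: dict[str, Any], prefix: str = "") -> list[tuple[str, str]]:
    paths = []
    for key, value in inputs.items():
        if isinstance(value, dict):
            paths.extend(_iter_input_paths(value, f"{prefix}{key}."))
        else:
            paths.append((f"{prefix}{key}", str(value)))
    return paths


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set, frozenset)):
        return [_jsonable(v) for v in sorted(obj)] if isinstance(obj, (set, frozenset)) else [
            _jsonable(v) for v in obj
        ]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, Path):
        return str(obj)
    return obj
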