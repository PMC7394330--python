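"""End-to-end analysis pipeline with a reproducible run manifest.

Stages: network build → optional GO weighting → module detection → size
distribution → enrichment → specificity → module profiles → optional pathway
validation.  Every stage writes a self-describing TSV; the manifest records
all parameters, input digests, seeds and the headline counts.  A second run
with the same config and seeds reproduces every output byte-identically
(timestamps are recorded only when explicitly supplied).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from . import __version__
from .detection import incremental_louvain, louvain, size_distribution
from .enrichment import DEFAULT_ALPHA, DEFAULT_MESOSCALE, enrich_partition
from .network import (
    ProteinNetwork,
    combine_networks,
    module_edge_density,
    network_summary,
    read_edge_list,
    write_edge_list,
)
from .ontology import parse_obo, read_annotations, write_annotations, write_obo
from .similarity import W_IS_A, W_PART_OF, weight_network
from .specificity import (
    SPECIFIC_THRESHOLD,
    heterogeneity_summary,
    homogeneity_summary,
    module_profiles,
    specificity_table,
)
from .synthetic import SyntheticConfig, generate, write_ground_truth
from .validation import overlap_table, read_gmt, write_gmt

logger = logging.getLogger(__name__)

_FLOAT_FMT = "%.10g"

DEFAULT_CONFIG: dict[str, Any] = {
    "network": None,          # edge-list path (or use "synthetic")
    "kind": "physical",
    "combine_with": None,     # optional second edge list to union in
    "obo": None,
    "annotations": None,
    "synthetic": None,        # SyntheticConfig fields; replaces file inputs
    "aspects": ["MF", "BP", "CC"],
    "weight_aspect": None,    # e.g. "MF": weight edges and detect on weights
    "aggregation": "bma",
    "w_is_a": W_IS_A,
    "w_part_of": W_PART_OF,
    "method": "louvain",      # or "incremental"
    "max_module_size": None,  # required for method=incremental
    "alpha": DEFAULT_ALPHA,
    "mesoscale": DEFAULT_MESOSCALE,
    "specific_threshold": SPECIFIC_THRESHOLD,
    "universe": "network",    # "network" or a gene-list file path
    "pathways": None,         # optional GMT path
    "seed": 0,
}


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def load_config(source: str | Path | Mapping[str, Any]) -> dict[str, Any]:
    """Merge a YAML file or mapping over the pipeline defaults."""
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            user = yaml.safe_load(fh) or {}
    else:
        user = dict(source)
    unknown = set(user) - set(DEFAULT_CONFIG)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    cfg = dict(DEFAULT_CONFIG)
    cfg.update(user)
    return cfg


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def run_pipeline(
    config: str | Path | Mapping[str, Any],
    out_dir: str | Path,
    timestamp: str | None = None,
) -> Path:
    """Execute the full analysis described by ``config`` into ``out_dir``.

    Returns the output directory.  On a stage failure, completed outputs are
    left in place and a ``FAILED`` marker names the failing stage.
    """
    cfg = load_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # -- validate inputs before any computation
    input_paths: dict[str, Path] = {}
    if cfg["synthetic"] is None:
        for key in ("network", "obo", "annotations"):
            if cfg[key] is None:
                raise ValueError(f"config requires {key!r} (or a 'synthetic' block)")
            input_paths[key] = Path(cfg[key])
        if cfg["combine_with"]:
            input_paths["combine_with"] = Path(cfg["combine_with"])
    if cfg["pathways"]:
        input_paths["pathways"] = Path(cfg["pathways"])
    if cfg["universe"] != "network":
        input_paths["universe"] = Path(cfg["universe"])
    missing = {k: str(p) for k, p in input_paths.items() if not p.exists()}
    if missing:
        raise FileNotFoundError(f"missing input file(s): {missing}")
    if cfg["method"] == "incremental" and not cfg["max_module_size"]:
        raise ValueError("method=incremental requires max_module_size (no silent default)")

    stage = "setup"
    try:
        # -- stage: inputs
        stage = "inputs"
        pathways = read_gmt(input_paths["pathways"]) if cfg["pathways"] else []
        if cfg["synthetic"] is not None:
            syn = dict(cfg["synthetic"])
            syn.setdefault("seed", cfg["seed"])
            if "aspects" in syn:
                syn["aspects"] = tuple(syn["aspects"])
            ds = generate(SyntheticConfig(**syn))
            net, dag, ann = ds.network, ds.dag, ds.annotations
            if not pathways:
                pathways = ds.pathways
            write_edge_list(net, out / "network.tsv")
            write_obo(dag, out / "ontology.obo")
            write_annotations(ann, out / "annotations.tsv")
            write_gmt(ds.pathways, out / "pathways.gmt")
            write_ground_truth(ds, out / "ground_truth.json")
        else:
            net = read_edge_list(input_paths["network"], kind=cfg["kind"])
            if "combine_with" in input_paths:
                other = read_edge_list(input_paths["combine_with"], kind="functional")
                net = combine_networks(net, other)
            dag = parse_obo(input_paths["obo"])
            ann = read_annotations(input_paths["annotations"], dag)
        logger.info("network %s: %d nodes, %d edges", net.name, net.node_count, net.edge_count)

        # -- stage: weighting
        stage = "weighting"
        use_weights = cfg["weight_aspect"] is not None
        if use_weights:
            net = weight_network(
                net, ann, dag, cfg["weight_aspect"],
                method=cfg["aggregation"], w_is_a=cfg["w_is_a"], w_part_of=cfg["w_part_of"],
            )
            write_edge_list(net, out / "weighted_network.tsv")

        # -- stage: summary
        stage = "network_summary"
        summ = network_summary(net, weighted=use_weights, seed=cfg["seed"])
        (out / "network_summary.tsv").write_text(summ.to_tsv())
        (out / "network_summary.json").write_text(summ.to_json() + "\n")

        # -- stage: detection
        stage = "module_detection"
        if cfg["method"] == "incremental":
            part = incremental_louvain(
                net, max_module_size=int(cfg["max_module_size"]),
                seed=cfg["seed"], use_weights=use_weights,
            )
        elif cfg["method"] == "louvain":
            part = louvain(net, seed=cfg["seed"], use_weights=use_weights)
        else:
            raise ValueError(f"unknown method {cfg['method']!r}")
        rows = sorted(part.assignment.items())
        _write_tsv(pd.DataFrame(rows, columns=["node", "module_id"]), out / "partition.tsv")
        (out / "partition.json").write_text(json.dumps(
            {"modularity": part.modularity, "method": part.method,
             "seed": part.seed, "params": part.params, "n_modules": len(part.modules)},
            indent=2, sort_keys=True) + "\n")
        dist = size_distribution(part, threshold=cfg["mesoscale"])
        _write_tsv(
            pd.DataFrame({"module_size": dist.sizes}),
            out / "size_distribution.tsv",
        )
        dens = module_edge_density(net, part.assignment)
        _write_tsv(
            pd.DataFrame(sorted(dens.items()), columns=["module_id", "edge_density"]),
            out / "module_density.tsv",
        )
        logger.info(
            "%s: Q=%.4f, %d modules, %d mesoscale (%.1f%%)",
            part.method, part.modularity, len(part.modules),
            dist.mesoscale_count, 100 * dist.mesoscale_fraction,
        )

        # -- stage: enrichment
        stage = "enrichment"
        if cfg["universe"] == "network":
            universe = net.nodes
        else:
            universe = {
                line.strip() for line in open(input_paths["universe"]) if line.strip()
            }
        table, fset = enrich_partition(
            part, ann, dag, universe=universe,
            alpha=cfg["alpha"], mesoscale_threshold=cfg["mesoscale"],
        )
        keep = [a for a in cfg["aspects"]]
        df = table.to_frame()
        df = df[df["aspect"].isin(keep)]
        _write_tsv(df, out / "enrichment.tsv")
        logger.info("enrichment: K=%d tested modules, |F|=%d", table.K, len(fset.F))

        # -- stage: specificity
        stage = "specificity"
        recs = specificity_table(table, fset)
        recs = [r for r in recs if r.aspect in keep]
        _write_tsv(
            pd.DataFrame([vars(r) for r in recs], columns=[
                "module_id", "term", "aspect", "homogeneity", "heterogeneity",
                "raw_specificity", "normalized_specificity"]),
            out / "specificity.tsv",
        )
        profiles = module_profiles(recs, threshold=cfg["specific_threshold"])
        prof_rows = []
        for p in profiles:
            row: dict[str, Any] = {"module_id": p.module_id,
                                   "module_specificity": p.module_specificity,
                                   "label": p.label}
            for asp in keep:
                row[f"H_{asp}"] = p.functional_homogeneity.get(asp)
            prof_rows.append(row)
        _write_tsv(pd.DataFrame(prof_rows), out / "module_profiles.tsv")
        if profiles:
            _write_tsv(homogeneity_summary(profiles), out / "homogeneity_summary.tsv")
        if recs:
            _write_tsv(heterogeneity_summary(recs), out / "heterogeneity_summary.tsv")
        n_spec = sum(1 for p in profiles if p.label == "specific")
        logger.info(
            "specificity: %d/%d profiled modules specific (%.0f%%)",
            n_spec, len(profiles), 100 * n_spec / len(profiles) if profiles else 0.0,
        )

        # -- stage: validation
        stage = "pathway_validation"
        if pathways:
            vdf = overlap_table(pathways, profiles, part, net)
            _write_tsv(vdf, out / "pathway_validation.tsv")
        else:
            logger.info("no pathway sets supplied; validation stage skipped")

        # -- manifest
        stage = "manifest"
        manifest = {
            "tool": "funcspec",
            "version": __version__,
            "timestamp": timestamp,
            "config": {k: (str(v) if isinstance(v, Path) else v) for k, v in cfg.items()},
            "input_digests": {k: _sha256(p) for k, p in input_paths.items()},
            "counts": {
                "nodes": net.node_count,
                "edges": net.edge_count,
                "n_modules": len(part.modules),
                "modularity": part.modularity,
                "mesoscale_modules": dist.mesoscale_count,
                "tested_modules_K": table.K,
                "enriched_functions_F": len(fset.F),
                "specific_modules": n_spec,
            },
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    except Exception as exc:
        (out / "FAILED").write_text(f"stage: {stage}\nerror: {exc}\n")
        raise
    return out
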