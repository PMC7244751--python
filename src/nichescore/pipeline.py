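"""End-to-end orchestration: QC -> normalization -> composition ->
markers -> enrichment -> contribution, as one reproducible run.

``analyze`` is the in-memory core used by tests and the acceptance
script; ``run_all`` is the file-driven wrapper behind the ``run-all``
CLI subcommand. A single seed governs the simulated inputs; every stage
after simulation is deterministic given its inputs.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from nichescore import io_resources as ior
from nichescore.composition import changed_subtypes, subtype_proportions
from nichescore.containers import CountMatrix
from nichescore.enrichment import maturation_pathways
from nichescore.interactome import (
    ContributionReport,
    contribution_report,
    select_receptors,
)
from nichescore.markers import MarkerParams, find_markers
from nichescore.qc import QCParams, filter_cells, filter_genes, normalize
from nichescore.synthetic import ResourceBundle, SimConfig, default_config, simulate

log = logging.getLogger(__name__)


@dataclass
class AnalysisParams:
    """All stage thresholds, with the standard defaults."""

    qc: QCParams = field(default_factory=QCParams)
    markers: MarkerParams = field(default_factory=MarkerParams)
    q_secretome: float = 1e-3
    composition_cutoff: float = 0.10
    enrich_p_cutoff: float = 0.05
    receptor_q_cutoff: float = 0.05
    receptor_contrast: str = "mature"   # "mature" (t1 cells only) or "pooled"
    t0: str = "P1"
    t1: str = "P56"
    target_cell_type: str = "CM"


@dataclass
class AnalysisResult:
    """Everything one analyze() run produced, stage by stage."""

    qc_report: object
    norm: object
    metadata: pd.DataFrame
    composition: pd.DataFrame
    changes: pd.DataFrame
    marker_table: pd.DataFrame
    maturation: list
    report: ContributionReport
    dims: dict


def analyze(counts: CountMatrix, metadata: pd.DataFrame, bundle: ResourceBundle,
            params: AnalysisParams | None = None,
            maturation=None, deg_genes=None) -> AnalysisResult:
    """Run the full contribution analysis on one dataset.

    ``maturation`` may be a list of set ids; when None, it is derived by
    hypergeometric enrichment of ``deg_genes`` (default: the bundle's
    maturation-trajectory DEG list) against the gene-set collection.
    """
    params = params or AnalysisParams()
    dims = {"input": {"genes": counts.n_genes, "cells": counts.n_cells}}

    counts_f, meta_f, qc_report = filter_cells(counts, metadata, params.qc)
    counts_f = filter_genes(counts_f, bundle.annotations.mitochondrial,
                            min_cells=params.qc.min_cells_per_gene)
    norm = normalize(counts_f, size_factor=params.qc.size_factor)
    dims["post_qc"] = {"genes": counts_f.n_genes, "cells": counts_f.n_cells}

    comp = subtype_proportions(meta_f)
    changes = changed_subtypes(comp, params.t0, params.t1,
                               cutoff=params.composition_cutoff)
    changed_ids = changes.loc[changes["changed"], "subtype"].tolist()
    dims["changed_subtypes"] = len(changed_ids)

    subtype_labels = meta_f["subtype"].to_numpy(dtype=object)
    marker_table = find_markers(norm, subtype_labels, params.markers,
                                groups=changed_ids or None)

    if maturation is None:
        if deg_genes is None:
            deg_genes = bundle.maturation_deg_genes
        set_genes = bundle.gene_sets.all_member_genes()
        universe = set(norm.gene_ids) & set_genes
        maturation = maturation_pathways(deg_genes, bundle.gene_sets, universe,
                                         p_cutoff=params.enrich_p_cutoff)
    dims["maturation_pathways"] = len(maturation)

    # target receptors: target-vs-rest markers intersected with membrane list
    if params.receptor_contrast == "mature":
        mask = (meta_f["time_point"] == params.t1).to_numpy()
        norm_r = norm.__class__(norm.gene_ids, norm.cell_ids[mask],
                                norm.values[:, np.flatnonzero(mask)],
                                size_factor=norm.size_factor)
        type_labels = meta_f.loc[mask, "cell_type"].to_numpy(dtype=object)
    else:
        norm_r = norm
        type_labels = meta_f["cell_type"].to_numpy(dtype=object)
    receptor_markers = find_markers(norm_r, type_labels, params.markers,
                                    groups=[params.target_cell_type])
    receptors = select_receptors(receptor_markers,
                                 bundle.annotations.membrane,
                                 q_cutoff=params.receptor_q_cutoff,
                                 target=params.target_cell_type,
                                 contrast=params.receptor_contrast)
    dims["receptors"] = len(receptors.genes)

    report = contribution_report(norm, subtype_labels, marker_table, changes,
                                 bundle.gene_sets, maturation,
                                 bundle.annotations.secreted, receptors,
                                 bundle.interactions,
                                 q_secretome=params.q_secretome)
    dims["ligand_pathway_edges"] = len(report.network)
    dims["lr_pairs"] = int(report.pair_counts.sum()) if len(report.pair_counts) else 0

    return AnalysisResult(qc_report=qc_report, norm=norm, metadata=meta_f,
                          composition=comp, changes=changes,
                          marker_table=marker_table, maturation=list(maturation),
                          report=report, dims=dims)


# ---------------------------------------------------------------------------
# file-driven run
# ---------------------------------------------------------------------------

RESOURCE_KEYS = ("counts", "metadata", "secreted", "membrane", "mito",
                 "gene_sets", "ppi")


def load_run_config(path: str | Path) -> dict:
    with open(path) as fh:
        config = yaml.safe_load(fh) or {}
    return config


def _params_from_config(config: dict) -> AnalysisParams:
    p = AnalysisParams()
    if "qc" in config:
        p.qc = QCParams(**config["qc"])
    if "markers" in config:
        p.markers = MarkerParams(**config["markers"])
    for key in ("q_secretome", "composition_cutoff", "enrich_p_cutoff",
                "receptor_q_cutoff", "receptor_contrast", "t0", "t1",
                "target_cell_type"):
        if key in config:
            setattr(p, key, config[key])
    return p


def preflight(config: dict) -> None:
    """Validate a file-driven run config before any computation."""
    if "simulate" in config:
        return
    missing_keys = [k for k in RESOURCE_KEYS if k not in config.get("inputs", {})]
    if missing_keys:
        raise ValueError("run config missing input path(s): "
                         + ", ".join(missing_keys))
    missing_files = [str(v) for v in config["inputs"].values()
                     if not Path(v).exists()]
    if missing_files:
        raise FileNotFoundError("missing input file(s): "
                                + ", ".join(missing_files))


def run_all(config: dict, outdir: str | Path) -> dict:
    """Execute every stage and write result tables plus a JSON run report.

    The config either carries a ``simulate`` block (seed + optional
    SimConfig overrides) or an ``inputs`` block of file paths. Returns
    the run report dict.
    """
    t_start = time.perf_counter()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    preflight(config)

    if "simulate" in config:
        sim_block = dict(config["simulate"] or {})
        seed = int(sim_block.pop("seed", 0))
        sim_config = default_config(seed=seed)
        for key, value in sim_block.items():
            if not hasattr(sim_config, key):
                raise ValueError(f"unknown simulate option: {key}")
            setattr(sim_config, key, value)
        counts, metadata, bundle, truth = simulate(sim_config)
        seed_note = seed
    else:
        inputs = config["inputs"]
        counts = ior.read_counts(inputs["counts"])
        metadata = ior.read_metadata(inputs["metadata"])
        bundle = ResourceBundle(
            gene_sets=ior.read_gene_sets(inputs["gene_sets"]),
            annotations=ior.read_annotations(
                inputs["secreted"], inputs["membrane"], inputs["mito"],
                inputs.get("housekeeping")),
            interactions=ior.read_interactions(
                inputs["ppi"], min_evidence=config.get("min_evidence", 0.0)),
            maturation_deg_genes=tuple(
                ior.read_gene_list(inputs["deg"])) if "deg" in inputs else (),
        )
        truth = None
        seed_note = config.get("seed")

    params = _params_from_config(config)
    maturation = config.get("maturation")
    result = analyze(counts, metadata, bundle, params, maturation=maturation)

    echo = [f"seed={seed_note}", f"qc={asdict(params.qc)}",
            f"markers={asdict(params.markers)}",
            f"q_secretome={params.q_secretome}",
            f"composition_cutoff={params.composition_cutoff}",
            f"enrich_p_cutoff={params.enrich_p_cutoff}"]
    ior.write_table(result.composition, outdir / "composition.tsv", echo)
    ior.write_table(result.changes, outdir / "changes.tsv", echo)
    ior.write_table(result.marker_table, outdir / "markers.tsv", echo)
    ior.write_table(result.report.network, outdir / "network_edges.tsv", echo)
    ior.write_table(result.report.zsum, outdir / "zsum_ranking.tsv", echo)
    ior.write_table(result.report.pairs, outdir / "lr_pairs.tsv", echo)
    counts_json = {str(k): int(v) for k, v in result.report.pair_counts.items()}

    run_report = {
        "seed": seed_note,
        "parameters": {"qc": asdict(params.qc), "markers": asdict(params.markers),
                       "q_secretome": params.q_secretome,
                       "composition_cutoff": params.composition_cutoff,
                       "enrich_p_cutoff": params.enrich_p_cutoff,
                       "receptor_contrast": params.receptor_contrast},
        "dimensions": result.dims,
        "qc_removed": result.qc_report.removed,
        "maturation_pathways": result.maturation,
        "pair_counts": counts_json,
        "warnings": list(result.qc_report.warnings),
        "wall_time_s": round(time.perf_counter() - t_start, 3),
    }
    if truth is not None:
        run_report["ground_truth"] = {
            "expected_top_contributor": truth.expected_top_contributor,
            "changed_subtypes": truth.changed_subtypes,
            "n_planted_pairs": len(truth.ligand_receptor_pairs),
        }
    with open(outdir / "contribution_report.json", "w") as fh:
        json.dump(run_report, fh, indent=2)
    return run_report
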