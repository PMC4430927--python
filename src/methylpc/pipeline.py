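"""End-to-end analysis pipeline: filter -> PCA -> associate -> deflate ->
concordance -> enrich -> cluster, driven by a single config with one seed.

Every numeric table in the report is regenerable from the inputs plus the
seed; stage failures halt the run and the report records the completed
stages.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import association, clustering, concordance, enrichment
from .io import (
    FilterLists,
    ProbeAnnotation,
    SampleMeta,
    assign_probes_to_lone_genes,
    compute_lone_genes,
    filter_probes,
    load_filter_list,
    load_gene_models,
    load_matrix,
    load_probe_annotation,
    load_sample_meta,
)
from .pca import fit_pca
from .simulate import BRAIN_TISSUES


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    matrix_path: str
    meta_path: str
    annotation_path: str
    genes_path: str
    snp_probes_path: str | None = None
    cross_hybridizing_path: str | None = None
    detection_alpha: float = 0.01
    min_beads: int = 3
    remove_offset: bool = True
    n_report_pcs: int = 5
    traits: tuple = ("age",)
    concordance_start_after_pc: int = 3
    concordance_alpha: float = 0.01
    enrichment_sigma_category: float = 1.0
    enrichment_sigma_genes: float = 2.0
    cluster_variance_sigma: float = 4.0
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def validate(self):
        for name in ("matrix_path", "meta_path", "annotation_path", "genes_path"):
            p = getattr(self, name)
            if not Path(p).exists():
                raise PipelineError(f"{name} does not exist: {p}")


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages; returns a JSON-serializable report."""
    config.validate()
    report = {"parameters": {k: v for k, v in vars(config).items()},
              "seed": config.seed, "stages": [], "warnings": []}
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        _run_stages(config, report)
        report["warnings"] = [str(w.message) for w in caught]
    return report


def _run_stages(config: PipelineConfig, report: dict):
    stage = "load"
    try:
        matrix = load_matrix(config.matrix_path)
        meta = load_sample_meta(config.meta_path).aligned_to(matrix.sample_ids)
        annotation = load_probe_annotation(config.annotation_path)
        genes = load_gene_models(config.genes_path)
        report["stages"].append(stage)

        stage = "filter"
        filters = FilterLists(
            snp_probes=load_filter_list(config.snp_probes_path)
            if config.snp_probes_path else set(),
            cross_hybridizing=load_filter_list(config.cross_hybridizing_path)
            if config.cross_hybridizing_path else set(),
        )
        matrix, removal_log = filter_probes(
            matrix, annotation, filters, config.detection_alpha, config.min_beads
        )
        report["filter"] = {"removal_log": removal_log, "n_probes": matrix.n_probes}
        report["stages"].append(stage)

        stage = "pca"
        result = fit_pca(matrix, remove_offset=config.remove_offset)
        k = min(config.n_report_pcs, result.n_components)
        report["pca"] = {
            "n_components": result.n_components,
            "offset_detected": result.offset_detected,
            "offset_fraction": result.offset_fraction,
            "eigenvalues": result.eigenvalues[:k].tolist(),
            "explained_fraction": result.explained_fraction[:k].tolist(),
        }
        report["stages"].append(stage)

        stage = "associate"
        tissue_vec = meta.table["tissue"].isin(BRAIN_TISSUES)
        subsets = {"all": np.ones(len(meta.table), dtype=bool)}
        if tissue_vec.any() and (~tissue_vec).any():
            subsets["brain"] = tissue_vec.to_numpy()
            subsets["blood"] = (~tissue_vec).to_numpy()
        traits = [t for t in config.traits if t in meta.table.columns]
        assoc = association.associate_all_pcs(result, meta, traits, subsets)
        report["association"] = assoc.head(50).to_dict("records")
        report["stages"].append(stage)

        stage = "batch_scan"
        if {"chip", "chip_position"} <= set(meta.table.columns):
            scan = association.batch_effect_scan(result, meta)
            report["batch_scan"] = {
                "n_tests": len(scan),
                "n_significant": int(scan["significant"].sum()),
            }
        report["stages"].append(stage)

        stage = "concordance"
        if result.n_components > config.concordance_start_after_pc:
            try:
                table, summary = concordance.select_concordant_pcs(
                    result, meta, config.concordance_start_after_pc,
                    config.concordance_alpha,
                )
                report["concordance"] = {
                    "summary": summary,
                    "records": table.to_dict("records"),
                }
            except concordance.ConcordanceError as exc:
                report["concordance"] = {"skipped": str(exc)}
        report["stages"].append(stage)

        stage = "enrichment"
        lone = compute_lone_genes(genes)
        probe_gene_map = assign_probes_to_lone_genes(annotation, genes, lone)
        background = set(matrix.probe_ids)
        enr = {}
        for pc in range(1, k + 1):
            tails = result.select_probes(pc, config.enrichment_sigma_category, "both")
            per_pc = {}
            for side in ("positive", "negative"):
                if not tails[side]:
                    continue
                cat = enrichment.category_enrichment(
                    tails[side], background, annotation, "density_class"
                )
                per_pc[side] = cat.to_dict("records")
            enr[f"pc{pc}"] = per_pc
        report["enrichment"] = {
            "n_lone_genes": len(lone),
            "n_probes_near_lone_tss": len(probe_gene_map),
            "density_class": enr,
        }
        report["stages"].append(stage)

        stage = "cluster"
        from .pca import select_high_variance_probes

        hv = select_high_variance_probes(matrix, config.cluster_variance_sigma)
        if len(hv) >= 1:
            dendro = clustering.single_linkage(matrix, hv)
            rep = clustering.cluster_report(dendro, meta, "tissue")
            report["cluster"] = {
                "n_probes": len(hv),
                "tissue_purity": rep["purity"],
                "newick": dendro.to_newick(),
            }
        report["stages"].append(stage)
    except Exception as exc:
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc


def write_report(report: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, default=_jsonify)


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (set, frozenset, tuple)):
        return list(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return str(obj)
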