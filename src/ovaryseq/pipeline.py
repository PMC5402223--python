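"""End-to-end orchestration: simulate -> dedup -> quantify/classify ->
enrich -> graph -> qPCR, with a JSON run manifest for reproducibility.

Stages are independent where the data allow it: deduplication consumes the
FASTQ input while quantification consumes the count table, so disabling
one never blocks the other. Given the same configuration and seed, every
stage output file is byte-identical across runs; the manifest carries wall
-clock timestamps and is the one run artifact excluded from that guarantee.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

from . import __version__
from .config import (
    OvaryseqError,
    PipelineConfig,
    config_to_dict,
    validate_config,
)
from . import dedup as dedup_mod
from . import enrichment as enrich_mod
from . import gograph, qpcr, quant, simulate

logger = logging.getLogger(__name__)


@dataclass
class RunManifest:
    """Snapshot of one pipeline run: config, stage record counts, version."""

    config: dict
    stages: dict = field(default_factory=dict)
    version: str = __version__
    started: str = ""
    finished: str = ""

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


def _now() -> str:
    return datetime.now(timezone.utc).isoformat()


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Run all enabled stages, writing outputs and a manifest to out_dir."""
    validate_config(config)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=config_to_dict(config), started=_now())

    paths = {
        "fastq": config.fastq_path,
        "counts": config.counts_path,
        "models": config.models_path,
        "obo": config.obo_path,
        "annotations": config.annotations_path,
        "qpcr": config.qpcr_path,
    }

    stage = "simulate"
    try:
        if config.run_simulate:
            sim_cfg = dataclasses.replace(config.sim, seed=config.seed)
            sim_paths = simulate.simulate_all(sim_cfg, out / "inputs")
            paths.update(
                fastq=sim_paths["reads.fastq"],
                counts=sim_paths["counts.tsv"],
                models=sim_paths["models.tsv"],
                obo=sim_paths["go.obo"],
                annotations=sim_paths["annotations.tsv"],
                qpcr=sim_paths["qpcr_ct.tsv"],
            )
            manifest.stages["simulate"] = {
                "n_genes": sim_cfg.n_genes,
                "n_go_terms": sim_cfg.n_go_terms,
                "n_reads_written": sum(1 for _ in open(sim_paths["reads.fastq"])) // 4,
            }
            logger.info("simulate: wrote synthetic inputs to %s", out / "inputs")

        if config.run_dedup and paths["fastq"]:
            stage = "dedup"
            report = dedup_mod.dedup_fastq(
                paths["fastq"],
                out / "kept.fastq",
                out / "dedup_report.tsv",
                config.dedup,
            )
            manifest.stages["dedup"] = {
                "n_input": report.n_input,
                "n_kept": report.n_kept,
                "n_removed": report.n_removed,
            }
            logger.info(
                "dedup: %d reads in, %d kept, %d removed",
                report.n_input, report.n_kept, report.n_removed,
            )

        classes = None
        if config.run_quant and paths["counts"] and paths["models"]:
            stage = "quantify"
            counts = quant.read_counts(paths["counts"])
            models = quant.read_models(paths["models"])
            fpkm = quant.fpkm_table(counts, models, config.replicate_mode)
            quant.write_fpkm(fpkm, out / "fpkm.tsv")
            expressed = quant.filter_expressed(fpkm, config.expressed_threshold)
            classes = quant.classify_table(
                fpkm,
                config.expressed_threshold,
                config.up_ratio,
                config.down_ratio,
                config.universe,
            )
            quant.write_classes(classes, out / "de_classes.tsv")
            class_counts = classes["de_class"].value_counts().to_dict()
            manifest.stages["quantify"] = {
                "n_genes": int(fpkm.shape[0]),
                "n_expressed_premature": len(expressed.get(quant.PREMATURE, ())),
                "n_expressed_mature": len(expressed.get(quant.MATURE, ())),
                "n_universe": int(classes.shape[0]),
                "n_premature_up": int(class_counts.get(quant.CLASS_PRE_UP, 0)),
                "n_mature_up": int(class_counts.get(quant.CLASS_MAT_UP, 0)),
                "n_neither": int(class_counts.get(quant.CLASS_NEITHER, 0)),
            }
            logger.info(
                "quantify: %(n_universe)d genes in universe, "
                "%(n_premature_up)d premature-up, %(n_mature_up)d mature-up",
                manifest.stages["quantify"],
            )

        results = None
        dag = None
        if (
            config.run_enrichment
            and classes is not None
            and paths["obo"]
            and paths["annotations"]
        ):
            stage = "enrich"
            dag = enrich_mod.load_obo(paths["obo"])
            annotations = enrich_mod.read_annotations(paths["annotations"])
            pre = set(classes.loc[classes["de_class"] == quant.CLASS_PRE_UP, "gene_id"])
            mat = set(classes.loc[classes["de_class"] == quant.CLASS_MAT_UP, "gene_id"])
            results = enrich_mod.compute_enrichment(
                dag, annotations, pre, mat,
                config.pseudo_count, config.pseudo_placement, config.propagate,
            )
            enrich_mod.write_enrichment(results, out / "enrichment.tsv")
            manifest.stages["enrich"] = {"n_terms": int(results.shape[0])}
            logger.info("enrich: scored %d GO terms", results.shape[0])

        if config.run_graph and results is not None and dag is not None:
            stage = "graph"
            graph = gograph.build_enrichment_graph(
                dag, results, config.min_level, config.min_genes, config.sig_threshold
            )
            gograph.export_graph(graph, out / "enrichment_graph")
            manifest.stages["graph"] = {
                "n_nodes": graph.number_of_nodes(),
                "n_edges": graph.number_of_edges(),
            }
            logger.info(
                "graph: %d nodes, %d edges",
                graph.number_of_nodes(), graph.number_of_edges(),
            )

        if config.run_qpcr and paths["qpcr"]:
            stage = "qpcr"
            ct = qpcr.read_ct_table(paths["qpcr"])
            fc, excluded = qpcr.quantify_table(ct, config.efficiency, config.ct_cap)
            qpcr.write_results(fc, out / "qpcr_results.tsv")
            manifest.stages["qpcr"] = {
                "n_results": int(fc.shape[0]),
                "n_excluded": int(excluded.shape[0]),
            }
            logger.info(
                "qpcr: %d genes quantified, %d non-detects excluded",
                fc.shape[0], excluded.shape[0],
            )
    except OvaryseqError:
        raise
    except Exception as exc:  # partial outputs stay on disk for inspection
        raise OvaryseqError(f"stage '{stage}' failed: {exc}") from exc

    manifest.finished = _now()
    (out / "manifest.json").write_text(manifest.to_json())
    return manifest
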