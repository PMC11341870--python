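"""End-to-end orchestration: scan -> classify -> summarize, one genome at a
time, with stage-count logging and a fully resolved, serializable
configuration."""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from . import context as ctx_mod
from . import domain_arch, genome_io, kkp_scan
from .model import CONTEXT_CATEGORIES, ContextAnnotation, KKPCluster

log = logging.getLogger(__name__)

EXIT_OK = 0
EXIT_VALIDATION = 2
EXIT_IO = 3


@dataclass
class RunConfig:
    """Every tunable of the pipeline, with the package defaults."""

    pattern: str = "both"
    min_bp: int = kkp_scan.DEFAULT_MIN_BP
    max_bp: int = kkp_scan.DEFAULT_MAX_BP
    evalue_max: float = domain_arch.DEFAULT_EVALUE_MAX
    max_shared_aa: int = domain_arch.DEFAULT_MAX_SHARED_AA
    p4_window_genes: int = ctx_mod.DEFAULT_P4_WINDOW_GENES
    mge_window_genes: int = ctx_mod.DEFAULT_MGE_WINDOW_GENES
    mge_window_bp: int = ctx_mod.DEFAULT_MGE_WINDOW_BP
    prophage_containment: bool = False
    identity_threshold: float = 90.0
    identity_denominator: str = "columns"
    gene_column: str = "target"
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)


@dataclass
class GenomeInputs:
    """Input files for one genome."""

    genome_id: str
    gene_table: Path
    domtbl: Path
    prophage_bed: Optional[Path] = None
    mge_tsv: Optional[Path] = None
    taxon: Optional[str] = None


@dataclass
class RunResult:
    clusters: list[KKPCluster]
    annotations: list[ContextAnnotation]
    clusters_frame: pd.DataFrame
    contexts_frame: pd.DataFrame
    summary_frame: pd.DataFrame
    stage_counts: dict


def process_genome(inputs: GenomeInputs, config: RunConfig):
    """Scan and context-classify one genome; returns (clusters, annotations)."""
    table = genome_io.read_gene_table(inputs.gene_table, inputs.genome_id,
                                      taxon=inputs.taxon)
    hits = domain_arch.read_domain_hits(inputs.domtbl,
                                        gene_column=config.gene_column)
    archs = domain_arch.architectures_for_genome(
        hits, [g.gene_id for g in table.genes() if g.ftype == "CDS"],
        evalue_max=config.evalue_max, max_shared_aa=config.max_shared_aa,
    )
    clusters = kkp_scan.classify_clusters(
        table, archs, pattern=config.pattern,
        min_bp=config.min_bp, max_bp=config.max_bp,
    )
    intervals = []
    if inputs.prophage_bed and Path(inputs.prophage_bed).stat().st_size > 0:
        intervals = genome_io.read_intervals(inputs.prophage_bed, dialect="bed")
    mge = {}
    if inputs.mge_tsv and Path(inputs.mge_tsv).stat().st_size > 0:
        mge = genome_io.read_mge_table(inputs.mge_tsv, table)
    annotations = ctx_mod.annotate_contexts(
        clusters, table, archs, intervals, mge,
        p4_window_genes=config.p4_window_genes,
        mge_window_genes=config.mge_window_genes,
        mge_window_bp=config.mge_window_bp,
        require_containment=config.prophage_containment,
    )
    return clusters, annotations, table


def run_full(
    genome_inputs: list[GenomeInputs],
    config: RunConfig,
    out_dir,
) -> RunResult:
    """Full pipeline over a genome set; writes clusters.tsv, contexts.tsv,
    summary.tsv and the resolved config.  Results are a pure function of
    (config, inputs) and independent of genome processing order."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    all_clusters: list[KKPCluster] = []
    all_annotations: list[ContextAnnotation] = []
    taxa: dict[str, str] = {}
    for inputs in genome_inputs:
        try:
            clusters, annotations, table = process_genome(inputs, config)
        except Exception as exc:
            raise RuntimeError(
                f"stage failure on genome {inputs.genome_id}: {exc}"
            ) from exc
        all_clusters.extend(clusters)
        all_annotations.extend(annotations)
        if table.taxon:
            for c in clusters:
                taxa[c.cluster_id] = table.taxon
        log.info("genome %s: %d candidates, %d authentic",
                 inputs.genome_id, len(clusters),
                 sum(1 for c in clusters if c.status == "authentic"))

    n_cand = len(all_clusters)
    n_len = sum(1 for c in all_clusters if all(c.report.length_pass))
    n_arch = sum(1 for c in all_clusters
                 if all(c.report.length_pass) and c.report.architecture_pass)
    n_auth = sum(1 for c in all_clusters if c.status == "authentic")
    stage_counts = {
        "candidates": n_cand,
        "length_pass": n_len,
        "architecture_pass": n_arch,
        "authentic": n_auth,
        "contexts": {
            cat: sum(1 for a in all_annotations if a.category == cat)
            for cat in CONTEXT_CATEGORIES
        },
    }
    log.info("stage counts: %s", stage_counts)

    clusters_frame = genome_io.clusters_to_frame(all_clusters)
    contexts_frame = pd.DataFrame(
        [{"cluster_id": a.cluster_id, "category": a.category,
          "evidence": ";".join(
              f"{e.kind}:{e.identifier}:{e.distance_genes}:{e.distance_bp}"
              for e in a.evidence)}
         for a in all_annotations],
        columns=genome_io.CONTEXT_COLUMNS,
    ).sort_values("cluster_id").reset_index(drop=True)
    auth_ids = {c.cluster_id for c in all_clusters if c.status == "authentic"}
    summary_frame = ctx_mod.summarize_contexts(
        [a for a in all_annotations if a.cluster_id in auth_ids], taxa or None)

    genome_io.write_results(clusters_frame, out_dir / "clusters.tsv")
    genome_io.write_results(contexts_frame, out_dir / "contexts.tsv")
    genome_io.write_results(summary_frame, out_dir / "summary.tsv")
    genome_io.write_clusters_gff3(all_clusters, out_dir / "authentic.gff3")
    with open(out_dir / "config.json", "w") as fh:
        json.dump(config.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    with open(out_dir / "stage_counts.json", "w") as fh:
        json.dump(stage_counts, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return RunResult(
        clusters=all_clusters, annotations=all_annotations,
        clusters_frame=clusters_frame, contexts_frame=contexts_frame,
        summary_frame=summary_frame, stage_counts=stage_counts,
    )
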