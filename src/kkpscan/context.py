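"""Genomic-context classification of KKP clusters.

Categories, in precedence order:

1. ``prophage`` — the cluster span overlaps a predicted prophage interval
   (>=1 bp by default; prophage boundary predictions are imprecise).
2. ``P4_prophage`` — no prophage interval, but a Psu-role gene (phage P4
   polarity suppression protein, PF07455) lies within a rescue window of
   the cluster.  Automated prophage predictors frequently miss the small
   (~11 kb) P4 satellites, so the Psu marker rescues them.
3. ``MGE_linked`` — an annotated mobile-genetic-element gene lies within 5
   genes or 3000 bp of the cluster (OR semantics).
4. ``other`` — none of the above.
"""

from __future__ import annotations

from typing import Iterable, Optional

import pandas as pd

from .model import (
    CTX_MGE,
    CTX_OTHER,
    CTX_P4,
    CTX_PROPHAGE,
    ContextAnnotation,
    Evidence,
    GeneArchitecture,
    GenomeTable,
    Interval,
    KKPCluster,
    ROLE_PSU,
)

DEFAULT_P4_WINDOW_GENES = 20
DEFAULT_MGE_WINDOW_GENES = 5
DEFAULT_MGE_WINDOW_BP = 3000


def overlaps_prophage(
    cluster: KKPCluster,
    intervals: Iterable[Interval],
    require_containment: bool = False,
) -> list[Evidence]:
    """Prophage evidence: cluster span overlaps an interval by >=1 bp
    (or is fully contained, with ``require_containment``)."""
    s, e = cluster.candidate.span
    contig = cluster.candidate.contig_id
    out = []
    for iv in intervals:
        if iv.contig_id != contig:
            continue
        hit = (iv.start <= s and e <= iv.end) if require_containment \
            else iv.overlaps(s, e)
        if hit:
            out.append(Evidence(
                kind="prophage_interval",
                identifier=f"{iv.contig_id}:{iv.start}-{iv.end}",
            ))
    return out


def rescue_p4(
    cluster: KKPCluster,
    table: GenomeTable,
    archs: dict[str, GeneArchitecture],
    window_genes: int = DEFAULT_P4_WINDOW_GENES,
) -> list[Evidence]:
    """P4 evidence: a Psu-role gene within ``window_genes`` contig positions
    of any cluster gene."""
    contig = table.contigs.get(cluster.candidate.contig_id, [])
    idx = {g.index for g in cluster.candidate.genes}
    out = []
    for g in contig:
        arch = archs.get(g.gene_id)
        if arch is None or arch.role != ROLE_PSU:
            continue
        dist = min(abs(g.index - i) for i in idx)
        if 0 < dist <= window_genes:
            out.append(Evidence(kind="psu_gene", identifier=g.gene_id,
                                distance_genes=dist,
                                distance_bp=_bp_distance(cluster, g)))
    return out


def _bp_distance(cluster: KKPCluster, gene) -> int:
    s, e = cluster.candidate.span
    if gene.end < s:
        return s - gene.end - 1
    if gene.start > e:
        return gene.start - e - 1
    return 0


def mge_linked(
    cluster: KKPCluster,
    table: GenomeTable,
    mge: dict[str, str],
    window_genes: int = DEFAULT_MGE_WINDOW_GENES,
    window_bp: int = DEFAULT_MGE_WINDOW_BP,
) -> list[Evidence]:
    """MGE evidence: every MGE-annotated gene within ``window_genes`` contig
    positions of a cluster gene OR within ``window_bp`` of the cluster span
    (OR semantics); both distances are recorded."""
    contig_id = cluster.candidate.contig_id
    idx = {g.index for g in cluster.candidate.genes}
    cluster_ids = {g.gene_id for g in cluster.candidate.genes}
    out = []
    for g in table.contigs.get(contig_id, []):
        if g.gene_id in cluster_ids or g.gene_id not in mge:
            continue
        dist_genes = min(abs(g.index - i) for i in idx)
        dist_bp = _bp_distance(cluster, g)
        if dist_genes <= window_genes or dist_bp <= window_bp:
            out.append(Evidence(
                kind="mge_gene",
                identifier=f"{g.gene_id}:{mge[g.gene_id]}",
                distance_genes=dist_genes,
                distance_bp=dist_bp,
            ))
    return out


def assign_context(
    cluster: KKPCluster,
    prophage_evidence: list[Evidence],
    psu_evidence: list[Evidence],
    mge_evidence: list[Evidence],
) -> ContextAnnotation:
    """Resolve evidence into a category by precedence
    prophage > P4_prophage > MGE_linked > other; all evidence is retained."""
    evidence = prophage_evidence + psu_evidence + mge_evidence
    if prophage_evidence:
        category = CTX_PROPHAGE
    elif psu_evidence:
        category = CTX_P4
    elif mge_evidence:
        category = CTX_MGE
    else:
        category = CTX_OTHER
    return ContextAnnotation(cluster_id=cluster.cluster_id,
                             category=category, evidence=evidence)


def annotate_contexts(
    clusters: Iterable[KKPCluster],
    table: GenomeTable,
    archs: dict[str, GeneArchitecture],
    intervals: Iterable[Interval],
    mge: dict[str, str],
    p4_window_genes: int = DEFAULT_P4_WINDOW_GENES,
    mge_window_genes: int = DEFAULT_MGE_WINDOW_GENES,
    mge_window_bp: int = DEFAULT_MGE_WINDOW_BP,
    require_containment: bool = False,
) -> list[ContextAnnotation]:
    """Convenience driver: full evidence gathering + assignment per cluster."""
    intervals = list(intervals)
    out = []
    for c in clusters:
        out.append(assign_context(
            c,
            overlaps_prophage(c, intervals, require_containment),
            rescue_p4(c, table, archs, p4_window_genes),
            mge_linked(c, table, mge, mge_window_genes, mge_window_bp),
        ))
    return out


def summarize_contexts(
    annotations: Iterable[ContextAnnotation],
    taxa: Optional[dict[str, str]] = None,
) -> pd.DataFrame:
    """Counts and fractions per category, overall and per taxon.

    ``taxa`` maps cluster_id -> taxon label.  The overall rows also report
    the MGE-linked share of non-prophage clusters as an "x out of y"
    string (clusters in neither the prophage nor the P4 category).
    """
    annotations = list(annotations)
    rows = []

    def _block(subset, taxon_label):
        n = len(subset)
        counts = {c: 0 for c in (CTX_PROPHAGE, CTX_P4, CTX_MGE, CTX_OTHER)}
        for a in subset:
            counts[a.category] += 1
        non_prophage = counts[CTX_MGE] + counts[CTX_OTHER]
        for cat, cnt in counts.items():
            rows.append({
                "taxon": taxon_label,
                "category": cat,
                "count": cnt,
                "fraction": cnt / n if n else float("nan"),
                "mge_among_non_prophage":
                    f"{counts[CTX_MGE]} out of {non_prophage}"
                    if cat == CTX_MGE else "",
            })

    _block(annotations, "all")
    if taxa:
        by_taxon: dict[str, list[ContextAnnotation]] = {}
        for a in annotations:
            by_taxon.setdefault(taxa.get(a.cluster_id, "unknown"), []).append(a)
        for taxon in sorted(by_taxon):
            _block(by_taxon[taxon], taxon)
    return pd.DataFrame(
        rows, columns=["taxon", "category", "count", "fraction",
                       "mge_among_non_prophage"],
    )
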