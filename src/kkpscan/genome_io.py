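"""Readers and writers for genome annotations, intervals, and result tables.

Internal coordinates are 1-based inclusive (GFF3/GenBank convention).
BED input (0-based half-open) is converted on read.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd

from .model import GeneRecord, GenomeTable, Interval, KKPCluster, ValidationError

log = logging.getLogger(__name__)

INTERVAL_LABELS = ("prophage", "P4", "user")


class FormatError(ValueError):
    """A file does not parse under its declared format."""


# ---------------------------------------------------------------------------
# gene tables


def read_gene_table(path, genome_id: str, fmt: Optional[str] = None,
                    taxon: Optional[str] = None) -> GenomeTable:
    """Read an annotated genome (GFF3 or GenBank) into a :class:`GenomeTable`.

    ``fmt`` is ``'gff3'`` or ``'genbank'``; guessed from the suffix when
    omitted.  CDS features form the triplet-scan universe; tRNA/rRNA
    features are retained but excluded from scanning.
    """
    path = Path(path)
    if fmt is None:
        suffix = path.suffix.lower()
        fmt = "genbank" if suffix in (".gb", ".gbk", ".gbff", ".genbank") else "gff3"
    if fmt == "gff3":
        table = _read_gff3(path, genome_id, taxon)
    elif fmt == "genbank":
        table = _read_genbank(path, genome_id, taxon)
    else:
        raise ValueError(f"unknown gene-table format {fmt!r}")
    return table.finalize()


_KEPT_TYPES = {"CDS", "tRNA", "rRNA"}


def _read_gff3(path: Path, genome_id: str, taxon: Optional[str]) -> GenomeTable:
    import gffutils

    try:
        db = gffutils.create_db(
            str(path), ":memory:",
            merge_strategy="error",
            keep_order=True,
        )
    except Exception as exc:  # gffutils raises assorted exceptions on bad input
        raise FormatError(f"{path}: GFF3 parse failure: {exc}") from exc

    table = GenomeTable(genome_id, taxon=taxon)
    for feat in db.all_features():
        if feat.featuretype not in _KEPT_TYPES:
            continue
        gene_id = (feat.attributes.get("ID") or feat.attributes.get("locus_tag")
                   or [None])[0]
        if gene_id is None:
            raise FormatError(
                f"{path}: {feat.featuretype} feature at "
                f"{feat.seqid}:{feat.start}..{feat.end} has no ID/locus_tag"
            )
        product = (feat.attributes.get("product") or [None])[0]
        table.add(GeneRecord(
            gene_id=gene_id,
            contig_id=feat.seqid,
            start=feat.start,
            end=feat.end,
            strand=feat.strand if feat.strand in ("+", "-") else "+",
            ftype=feat.featuretype,
            product=product,
        ))
    return table


def _read_genbank(path: Path, genome_id: str, taxon: Optional[str]) -> GenomeTable:
    from Bio import SeqIO

    table = GenomeTable(genome_id, taxon=taxon)
    try:
        records = list(SeqIO.parse(str(path), "genbank"))
    except Exception as exc:
        raise FormatError(f"{path}: GenBank parse failure: {exc}") from exc
    for rec in records:
        for feat in rec.features:
            if feat.type not in _KEPT_TYPES:
                continue
            quals = feat.qualifiers
            gene_id = (quals.get("locus_tag") or quals.get("gene") or [None])[0]
            if gene_id is None:
                continue
            table.add(GeneRecord(
                gene_id=gene_id,
                contig_id=rec.id,
                # biopython locations are 0-based half-open
                start=int(feat.location.start) + 1,
                end=int(feat.location.end),
                strand="-" if feat.location.strand == -1 else "+",
                ftype=feat.type,
                product=(quals.get("product") or [None])[0],
            ))
    return table


# ---------------------------------------------------------------------------
# intervals (prophage regions)


def read_intervals(path, dialect: str = "bed", label: str = "prophage",
                   source: str = "") -> list[Interval]:
    """Read prophage/region intervals from BED (0-based half-open) or TSV
    (1-based inclusive); everything is normalized to 1-based inclusive."""
    if dialect not in ("bed", "tsv"):
        raise ValueError(f"unknown interval dialect {dialect!r}")
    out: list[Interval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: expected >=3 columns")
            contig, s, e = fields[0], fields[1], fields[2]
            try:
                start, end = int(s), int(e)
            except ValueError:
                raise FormatError(
                    f"{path}:{lineno}: non-integer coordinates {s!r}, {e!r}"
                ) from None
            if dialect == "bed":
                start += 1  # 0-based half-open -> 1-based inclusive
            lab = fields[3] if len(fields) > 3 else label
            if start < 1 or start > end:
                raise ValidationError(
                    f"{path}:{lineno}: bad interval {contig}:{start}..{end}"
                )
            out.append(Interval(contig, start, end, label=lab, source=source))
    if not out:
        log.warning("no intervals read from %s", path)
    return out


# ---------------------------------------------------------------------------
# MGE gene table


def read_mge_table(path, table: Optional[GenomeTable] = None) -> dict[str, str]:
    """Read a 2-column TSV (gene_id, MGE category).

    If a :class:`GenomeTable` is given, every gene_id must resolve in it.
    """
    mge: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise FormatError(f"{path}:{lineno}: expected 2 columns")
            gene_id, category = parts[0], parts[1]
            if table is not None and gene_id not in table:
                raise ValidationError(
                    f"{path}:{lineno}: MGE gene {gene_id!r} not in genome "
                    f"{table.genome_id!r}"
                )
            mge[gene_id] = category
    return mge


# ---------------------------------------------------------------------------
# neighborhood helpers


def neighbors(table: GenomeTable, gene_id: str, k: int) -> list[GeneRecord]:
    """Up to ``k`` genes on each side of ``gene_id`` by contig index,
    excluding the query itself; truncated at contig ends, no wraparound."""
    if k < 0:
        raise ValueError("k must be >= 0")
    gene = table.get(gene_id)
    contig = table.contigs[gene.contig_id]
    i = gene.index
    return contig[max(0, i - k):i] + contig[i + 1:i + 1 + k]


def intergenic_distance_bp(a: GeneRecord, b: GeneRecord) -> int:
    """Gap in bp between two genes on one contig; 0 if they overlap or abut."""
    if a.contig_id != b.contig_id:
        raise ValueError(
            f"genes {a.gene_id} and {b.gene_id} lie on different contigs"
        )
    lo, hi = (a, b) if a.start <= b.start else (b, a)
    return max(0, hi.start - lo.end - 1)


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# result tables

CLUSTER_COLUMNS = [
    "cluster_id", "genome_id", "contig_id", "start", "end", "strand",
    "pattern", "status", "gene1_id", "gene2_id", "gene3_id",
    "role1", "role2", "role3", "len1_bp", "len2_bp", "len3_bp",
    "pfpC_like", "pfkA_like", "pfkB_like",
    "length_pass", "architecture_pass", "reasons",
]

CONTEXT_COLUMNS = ["cluster_id", "category", "evidence"]


def clusters_to_frame(clusters: Iterable[KKPCluster]) -> pd.DataFrame:
    rows = []
    for c in clusters:
        cand, rep = c.candidate, c.report
        span = cand.span
        rows.append({
            "cluster_id": c.cluster_id,
            "genome_id": cand.genome_id,
            "contig_id": cand.contig_id,
            "start": span[0],
            "end": span[1],
            "strand": cand.strand,
            "pattern": cand.pattern,
            "status": c.status,
            "gene1_id": cand.genes[0].gene_id,
            "gene2_id": cand.genes[1].gene_id,
            "gene3_id": cand.genes[2].gene_id,
            "role1": cand.roles[0],
            "role2": cand.roles[1],
            "role3": cand.roles[2],
            "len1_bp": cand.genes[0].length_bp,
            "len2_bp": cand.genes[1].length_bp,
            "len3_bp": cand.genes[2].length_bp,
            "pfpC_like": c.pfpC_like or "",
            "pfkA_like": c.pfkA_like or "",
            "pfkB_like": c.pfkB_like or "",
            "length_pass": ";".join(str(p) for p in rep.length_pass),
            "architecture_pass": str(rep.architecture_pass),
            "reasons": ";".join(rep.reasons),
        })
    df = pd.DataFrame(rows, columns=CLUSTER_COLUMNS)
    return df.sort_values(
        ["genome_id", "contig_id", "start", "cluster_id"]
    ).reset_index(drop=True)


def write_results(df: pd.DataFrame, path, sort_by: Optional[list[str]] = None) -> None:
    """Write a result table as TSV with a deterministic column order and sort."""
    if sort_by:
        df = df.sort_values(sort_by).reset_index(drop=True)
    df.to_csv(path, sep="\t", index=False)


def read_results(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", keep_default_na=False,
                       na_values=[], dtype=str)


def write_clusters_gff3(clusters: Iterable[KKPCluster], path,
                        authentic_only: bool = True) -> None:
    """Export clusters as GFF3 features (one feature per cluster span)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        rows = sorted(
            (c for c in clusters if c.status == "authentic" or not authentic_only),
            key=lambda c: (c.candidate.genome_id, c.candidate.contig_id,
                           c.candidate.span[0]),
        )
        for c in rows:
            cand = c.candidate
            s, e = cand.span
            attrs = (
                f"ID={c.cluster_id};status={c.status};pattern={cand.pattern};"
                f"pfpC_like={c.pfpC_like or '.'};pfkA_like={c.pfkA_like or '.'};"
                f"pfkB_like={c.pfkB_like or '.'}"
            )
            fh.write(
                f"{cand.contig_id}\tkkpscan\tgene_cluster\t{s}\t{e}\t.\t"
                f"{cand.strand}\t.\t{attrs}\n"
            )
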