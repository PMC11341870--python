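"""Shared data model for the KKP-module mining pipeline.

A KKP module is a three-gene cluster encoding two Ser/Thr kinases (a
PfkA-like kinase with a C-terminal cold shock domain and a PfkB-like kinase
with a C-terminal forkhead-associated domain) plus a PP2C-family Ser/Thr
phosphatase (PfpC-like).  The pipeline mines annotated genomes for
consecutive same-strand phosphatase-kinase-kinase gene triplets, filters
them by gene length and kinase domain architecture, and classifies their
genomic context (prophage / P4 satellite / MGE-linked / other).

Coordinates are 1-based inclusive throughout (GFF3/GenBank convention);
BED input is converted on read.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

# ---------------------------------------------------------------------------
# role vocabulary

ROLE_PP2C = "PP2C"
ROLE_KINASE_CSD = "Pkinase_CSD"
ROLE_KINASE_FHA = "Pkinase_FHA"
ROLE_KINASE_PLAIN = "Pkinase_plain"
ROLE_PSU = "Psu"
ROLE_OTHER = "other"

ROLES = (
    ROLE_PP2C,
    ROLE_KINASE_CSD,
    ROLE_KINASE_FHA,
    ROLE_KINASE_PLAIN,
    ROLE_PSU,
    ROLE_OTHER,
)

KINASE_ROLES = frozenset({ROLE_KINASE_CSD, ROLE_KINASE_FHA, ROLE_KINASE_PLAIN})

# rejection codes for triplet candidates
LEN_SHORT = "LEN_SHORT"
LEN_LONG = "LEN_LONG"
NO_CSD = "NO_CSD"
NO_FHA = "NO_FHA"
DUP_ACCESSORY = "DUP_ACCESSORY"

# context categories
CTX_PROPHAGE = "prophage"
CTX_P4 = "P4_prophage"
CTX_MGE = "MGE_linked"
CTX_OTHER = "other"
CONTEXT_CATEGORIES = (CTX_PROPHAGE, CTX_P4, CTX_MGE, CTX_OTHER)

MGE_CATEGORIES = (
    "integrase",
    "transposase",
    "RM_system",
    "TA_system",
    "phage_gene",
    "other_MGE",
)


class ValidationError(ValueError):
    """Input violates a data-model invariant."""


@dataclass(frozen=True)
class GeneRecord:
    """One annotated gene (1-based inclusive coordinates)."""

    gene_id: str
    contig_id: str
    start: int
    end: int
    strand: str  # '+' or '-'
    index: int = -1  # 0-based rank on its contig, set by GenomeTable
    ftype: str = "CDS"  # feature type; only CDS enters the triplet scan
    protein_len_aa: Optional[int] = None
    product: Optional[str] = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValidationError(
                f"gene {self.gene_id}: start {self.start} > end {self.end}"
            )
        if self.start < 1:
            raise ValidationError(f"gene {self.gene_id}: start {self.start} < 1")
        if self.strand not in ("+", "-"):
            raise ValidationError(
                f"gene {self.gene_id}: strand must be '+' or '-', got {self.strand!r}"
            )

    @property
    def length_bp(self) -> int:
        return self.end - self.start + 1


class GenomeTable:
    """An annotated genome: ordered genes per contig, unique ids genome-wide.

    Genes on a contig are ordered by (start, end, gene_id) and indexed
    0..n-1 over all feature types; :meth:`cds` gives the protein-coding
    sublist that the triplet scanner operates on.
    """

    def __init__(self, genome_id: str, taxon: Optional[str] = None):
        self.genome_id = genome_id
        self.taxon = taxon
        self.contigs: dict[str, list[GeneRecord]] = {}
        self._by_id: dict[str, GeneRecord] = {}

    def add(self, gene: GeneRecord) -> None:
        if gene.gene_id in self._by_id:
            raise ValidationError(f"duplicate gene_id {gene.gene_id!r}")
        self.contigs.setdefault(gene.contig_id, []).append(gene)
        self._by_id[gene.gene_id] = gene

    def finalize(self) -> "GenomeTable":
        """Sort and index genes per contig; call once after all adds."""
        import dataclasses

        for contig_id, genes in self.contigs.items():
            genes.sort(key=lambda g: (g.start, g.end, g.gene_id))
            for i, g in enumerate(genes):
                if g.index != i:
                    g2 = dataclasses.replace(g, index=i)
                    genes[i] = g2
                    self._by_id[g.gene_id] = g2
        return self

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._by_id

    def __len__(self) -> int:
        return len(self._by_id)

    def get(self, gene_id: str) -> GeneRecord:
        try:
            return self._by_id[gene_id]
        except KeyError:
            raise KeyError(
                f"gene {gene_id!r} not found in genome {self.genome_id!r}"
            ) from None

    def genes(self):
        for contig_id in self.contigs:
            yield from self.contigs[contig_id]

    def cds(self, contig_id: str) -> list[GeneRecord]:
        return [g for g in self.contigs.get(contig_id, []) if g.ftype == "CDS"]


@dataclass(frozen=True)
class Interval:
    """A genomic interval, 1-based inclusive (e.g. a predicted prophage)."""

    contig_id: str
    start: int
    end: int
    label: str = "prophage"
    source: str = ""

    def __post_init__(self) -> None:
        if self.start < 1 or self.start > self.end:
            raise ValidationError(
                f"bad interval {self.contig_id}:{self.start}..{self.end}"
            )

    def overlaps(self, start: int, end: int) -> bool:
        return self.start <= end and start <= self.end


@dataclass(frozen=True)
class DomainHit:
    """One per-domain hit of a profile HMM on a protein."""

    gene_id: str
    accession: str
    name: str
    i_evalue: float
    bitscore: float
    ali_from: int
    ali_to: int

    def __post_init__(self) -> None:
        if self.ali_from > self.ali_to:
            raise ValidationError(
                f"hit {self.accession} on {self.gene_id}: "
                f"ali_from {self.ali_from} > ali_to {self.ali_to}"
            )
        if self.i_evalue < 0:
            raise ValidationError(f"negative i-Evalue on {self.gene_id}")


@dataclass(frozen=True)
class Segment:
    """One accepted, non-overlapping domain segment on a protein."""

    label: str
    ali_from: int
    ali_to: int
    bitscore: float


@dataclass(frozen=True)
class GeneArchitecture:
    """Resolved domain architecture and role of one gene."""

    gene_id: str
    segments: tuple[Segment, ...]
    role: str

    def labels(self) -> tuple[str, ...]:
        return tuple(s.label for s in self.segments)


@dataclass(frozen=True)
class TripletCandidate:
    """Three consecutive same-strand CDS whose roles read P-K-K (or K-K-P)
    in transcription order."""

    genome_id: str
    contig_id: str
    genes: tuple[GeneRecord, GeneRecord, GeneRecord]  # transcription order
    strand: str
    roles: tuple[str, str, str]
    pattern: str  # 'PKK' or 'KKP' (transcription-order pattern matched)

    @property
    def span(self) -> tuple[int, int]:
        starts = [g.start for g in self.genes]
        ends = [g.end for g in self.genes]
        return min(starts), max(ends)

    @property
    def index_triple(self) -> tuple[int, int, int]:
        return tuple(sorted(g.index for g in self.genes))  # type: ignore[return-value]


@dataclass
class FilterReport:
    """Per-filter outcome for one candidate; empty reasons iff accepted."""

    length_pass: tuple[bool, bool, bool] = (True, True, True)
    architecture_pass: bool = True
    reasons: list[str] = field(default_factory=list)

    @property
    def accepted(self) -> bool:
        return not self.reasons


@dataclass
class KKPCluster:
    """A classified phosphatase-kinase-kinase triplet."""

    candidate: TripletCandidate
    report: FilterReport
    pfpC_like: Optional[str] = None  # PP2C gene
    pfkA_like: Optional[str] = None  # CSD kinase
    pfkB_like: Optional[str] = None  # FHA kinase
    cluster_id: str = ""

    @property
    def status(self) -> str:
        return "authentic" if self.report.accepted else "rejected"


@dataclass(frozen=True)
class Evidence:
    """One piece of genomic-context evidence for a cluster."""

    kind: str  # prophage_interval | psu_gene | mge_gene
    identifier: str
    distance_genes: int = 0
    distance_bp: int = 0


@dataclass
class ContextAnnotation:
    """Genomic-context category of one cluster plus supporting evidence."""

    cluster_id: str
    category: str
    evidence: list[Evidence] = field(default_factory=list)


@dataclass(frozen=True)
class GapRun:
    """A maximal run of gap columns in one sequence of a pairwise alignment."""

    in_seq: str  # 'a' or 'b': which sequence carries the gap characters
    start_col: int  # 0-based alignment column where the run starts
    length: int
    flank: str  # up to 10 residues immediately 5' of the gap, ungapped coords


@dataclass
class AlignmentResult:
    """Global affine-gap pairwise alignment summary."""

    aligned_a: str
    aligned_b: str
    score: float
    columns: int
    matches: int
    mismatches: int
    gap_columns: int
    gap_runs: list[GapRun]

    @property
    def percent_identity(self) -> float:
        return 100.0 * self.matches / self.columns if self.columns else 0.0


@dataclass
class Family:
    """A single-linkage family of KKP clusters above an identity threshold."""

    family_id: str
    members: list[str]
    representative: str
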