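"""The core triplet-mining algorithm.

KKP modules are mined as consecutive, same-strand gene triplets whose roles
read phosphatase-kinase-kinase in transcription order, then filtered by
gene length (all three genes strictly between 900 and 1300 bp) and by
kinase domain architecture (exactly one CSD-fused and one FHA-fused kinase
between the two kinase genes).  A triplet passing every filter is an
"authentic" KKP cluster; every rejected candidate carries at least one
machine-readable rejection code.

Because the operon is named kinase-kinase-phosphatase while the search
pattern is most naturally stated phosphatase-first, the scanner accepts the
P-K-K transcription-order pattern, the K-K-P pattern, or both (default);
each candidate records which pattern matched.
"""

from __future__ import annotations

from typing import Iterable, Optional

from .model import (
    DUP_ACCESSORY,
    FilterReport,
    GeneArchitecture,
    GenomeTable,
    KINASE_ROLES,
    KKPCluster,
    LEN_LONG,
    LEN_SHORT,
    NO_CSD,
    NO_FHA,
    ROLE_KINASE_CSD,
    ROLE_KINASE_FHA,
    ROLE_PP2C,
    TripletCandidate,
)

DEFAULT_MIN_BP = 900
DEFAULT_MAX_BP = 1300
PATTERNS = ("PKK", "KKP", "both")


def scan_triplets(
    table: GenomeTable,
    archs: dict[str, GeneArchitecture],
    pattern: str = "both",
) -> list[TripletCandidate]:
    """Enumerate phosphatase-kinase-kinase triplet candidates.

    A candidate is three CDS at consecutive CDS ranks on one contig, all on
    one strand, whose roles read P-K-K (and/or K-K-P, per ``pattern``) in
    transcription order — ascending coordinates on '+', descending on '-'.
    Candidates are returned in coordinate order.
    """
    if pattern not in PATTERNS:
        raise ValueError(f"pattern must be one of {PATTERNS}")
    out: list[TripletCandidate] = []
    for contig_id in table.contigs:
        cds = table.cds(contig_id)
        for i in range(len(cds) - 2):
            window = cds[i:i + 3]
            strand = window[0].strand
            if any(g.strand != strand for g in window):
                continue
            roles = []
            for g in window:
                try:
                    roles.append(archs[g.gene_id].role)
                except KeyError:
                    raise KeyError(
                        f"gene {g.gene_id!r} has no architecture"
                    ) from None
            tx = window if strand == "+" else window[::-1]
            tx_roles = tuple(roles) if strand == "+" else tuple(roles[::-1])
            matched: Optional[str] = None
            if pattern in ("PKK", "both") and _is_pkk(tx_roles):
                matched = "PKK"
            elif pattern in ("KKP", "both") and _is_pkk(tx_roles[::-1]):
                matched = "KKP"
            if matched is None:
                continue
            out.append(TripletCandidate(
                genome_id=table.genome_id,
                contig_id=contig_id,
                genes=tuple(tx),  # type: ignore[arg-type]
                strand=strand,
                roles=tx_roles,
                pattern=matched,
            ))
    return out


def _is_pkk(roles: tuple[str, str, str]) -> bool:
    return (roles[0] == ROLE_PP2C
            and roles[1] in KINASE_ROLES
            and roles[2] in KINASE_ROLES)


def apply_length_filter(
    cand: TripletCandidate,
    min_bp: int = DEFAULT_MIN_BP,
    max_bp: int = DEFAULT_MAX_BP,
) -> FilterReport:
    """Strict per-gene length filter: pass iff min_bp < length < max_bp."""
    if min_bp >= max_bp:
        raise ValueError(f"min_bp {min_bp} must be < max_bp {max_bp}")
    passes = tuple(min_bp < g.length_bp < max_bp for g in cand.genes)
    reasons = []
    if any(g.length_bp <= min_bp for g in cand.genes):
        reasons.append(LEN_SHORT)
    if any(g.length_bp >= max_bp for g in cand.genes):
        reasons.append(LEN_LONG)
    return FilterReport(length_pass=passes, reasons=reasons)  # type: ignore[arg-type]


def apply_architecture_filter(cand: TripletCandidate) -> FilterReport:
    """Kinase accessory-domain filter.

    Passes iff exactly one of the two kinase genes is CSD-fused and the
    other FHA-fused; which kinase position carries which accessory is not
    constrained.
    """
    kin_roles = [r for r in cand.roles if r in KINASE_ROLES]
    n_csd = kin_roles.count(ROLE_KINASE_CSD)
    n_fha = kin_roles.count(ROLE_KINASE_FHA)
    reasons = []
    if n_csd == 0:
        reasons.append(NO_CSD)
    if n_fha == 0:
        reasons.append(NO_FHA)
    if n_csd > 1 or n_fha > 1:
        reasons.append(DUP_ACCESSORY)
    return FilterReport(architecture_pass=not reasons, reasons=reasons)


def classify_clusters(
    table: GenomeTable,
    archs: dict[str, GeneArchitecture],
    pattern: str = "both",
    min_bp: int = DEFAULT_MIN_BP,
    max_bp: int = DEFAULT_MAX_BP,
) -> list[KKPCluster]:
    """Scan, filter, and role-resolve every candidate into a KKPCluster."""
    clusters: list[KKPCluster] = []
    for cand in scan_triplets(table, archs, pattern=pattern):
        lrep = apply_length_filter(cand, min_bp=min_bp, max_bp=max_bp)
        arep = apply_architecture_filter(cand)
        report = FilterReport(
            length_pass=lrep.length_pass,
            architecture_pass=arep.architecture_pass,
            reasons=lrep.reasons + arep.reasons,
        )
        pfpC = pfkA = pfkB = None
        for g, role in zip(cand.genes, cand.roles):
            if role == ROLE_PP2C:
                pfpC = g.gene_id
            elif role == ROLE_KINASE_CSD and pfkA is None:
                pfkA = g.gene_id
            elif role == ROLE_KINASE_FHA and pfkB is None:
                pfkB = g.gene_id
        lo = min(g.index for g in cand.genes)
        hi = max(g.index for g in cand.genes)
        cluster_id = f"{cand.genome_id}|{cand.contig_id}|{lo}-{hi}"
        clusters.append(KKPCluster(
            candidate=cand, report=report, cluster_id=cluster_id,
            pfpC_like=pfpC, pfkA_like=pfkA, pfkB_like=pfkB,
        ))
    clusters.sort(key=lambda c: (c.candidate.genome_id, c.candidate.contig_id,
                                 c.candidate.span[0]))
    return clusters


def authentic_fraction(clusters: Iterable[KKPCluster]) -> Optional[float]:
    """Authentic clusters as a percentage of all candidates; ``None`` when
    there are no candidates (undefined, never reported as 0)."""
    clusters = list(clusters)
    if not clusters:
        return None
    n_auth = sum(1 for c in clusters if c.status == "authentic")
    return 100.0 * n_auth / len(clusters)
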