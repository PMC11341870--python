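"""Domain-hit ingestion, architecture resolution, and gene role calling.

The role vocabulary is built around five Pfam/COG families:

* Pkinase (PF00069 / COG0515) — eukaryotic-like Ser/Thr kinase domain
* PP2C (PF13672 / COG0631) — protein phosphatase 2C family domain
* CSD (PF00313) — cold shock domain, C-terminal accessory of PfkA-like kinases
* FHA (PF00498) — forkhead-associated domain, C-terminal accessory of
  PfkB-like kinases
* Psu (PF07455) — phage P4 polarity suppression protein, used downstream as
  a marker for P4 satellite prophages

"Fused with" a CSD/FHA is operationalized as the accessory segment starting
strictly after the kinase segment ends (variable C-termini); an N-terminal
accessory domain does not confer the fused role.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .model import (
    DomainHit,
    GeneArchitecture,
    ROLE_KINASE_CSD,
    ROLE_KINASE_FHA,
    ROLE_KINASE_PLAIN,
    ROLE_OTHER,
    ROLE_PP2C,
    ROLE_PSU,
    Segment,
)

log = logging.getLogger(__name__)

DEFAULT_VOCABULARY = {
    "PF00069": "Pkinase",
    "COG0515": "Pkinase",
    "PF13672": "PP2C",
    "COG0631": "PP2C",
    "PF00313": "CSD",
    "PF00498": "FHA",
    "PF07455": "Psu",
}

DEFAULT_EVALUE_MAX = 1e-5
DEFAULT_MAX_SHARED_AA = 15


@dataclass
class DomainVocabulary:
    """Accession -> canonical label mapping, user-extensible."""

    mapping: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_VOCABULARY))

    def label(self, accession: str) -> str:
        # Pfam accessions may carry a version suffix (PF00069.28)
        return self.mapping.get(accession.split(".")[0], accession)

    @classmethod
    def from_file(cls, path) -> "DomainVocabulary":
        """Extend the defaults from a 2-column file (accession, label)."""
        vocab = cls()
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                acc, label = line.split()[:2]
                vocab.mapping[acc] = label
        return vocab


def read_domain_hits(path, gene_column: str = "target") -> list[DomainHit]:
    """Parse an HMMER3 per-domain table (``--domtblout`` dialect).

    ``gene_column`` names the column that carries the gene id: ``'target'``
    (hmmsearch against a protein database: targets are genes) or
    ``'query'`` (hmmscan of gene sequences against a profile database).
    """
    if gene_column not in ("target", "query"):
        raise ValueError("gene_column must be 'target' or 'query'")
    hits: list[DomainHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            f = line.split(None, 22)
            if len(f) < 22:
                raise ValueError(
                    f"{path}:{lineno}: expected >=22 whitespace-delimited "
                    f"columns, got {len(f)}"
                )
            if gene_column == "target":
                gene_id, acc, name = f[0], f[4], f[3]
            else:
                gene_id, acc, name = f[3], f[1], f[0]
            try:
                i_evalue = float(f[12])
                bitscore = float(f[13])
                ali_from = int(f[17])
                ali_to = int(f[18])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: bad numeric field: {exc}") from None
            hits.append(DomainHit(
                gene_id=gene_id, accession=acc, name=name,
                i_evalue=i_evalue, bitscore=bitscore,
                ali_from=ali_from, ali_to=ali_to,
            ))
    return hits


def build_architecture(
    hits: list[DomainHit],
    vocab: DomainVocabulary | None = None,
    evalue_max: float = DEFAULT_EVALUE_MAX,
    max_shared_aa: int = DEFAULT_MAX_SHARED_AA,
    gene_id: str | None = None,
) -> GeneArchitecture:
    """Resolve one gene's hits into non-overlapping segments and a role.

    Hits above ``evalue_max`` (independent E-value) are dropped; survivors
    are accepted greedily by descending bitscore, rejecting any hit that
    overlaps an already accepted segment by more than ``max_shared_aa``
    residues.  The greedy order ties on (bitscore desc, ali_from, ali_to,
    accession), making the result independent of input order.
    """
    if vocab is None:
        vocab = DomainVocabulary()
    ids = {h.gene_id for h in hits}
    if len(ids) > 1:
        raise ValueError(f"hits span multiple genes: {sorted(ids)}")
    if gene_id is None:
        if not ids:
            raise ValueError("no hits and no gene_id given")
        gene_id = next(iter(ids))

    kept = [h for h in hits if h.i_evalue <= evalue_max]
    kept.sort(key=lambda h: (-h.bitscore, h.ali_from, h.ali_to, h.accession))
    accepted: list[DomainHit] = []
    for h in kept:
        clash = False
        for a in accepted:
            shared = min(h.ali_to, a.ali_to) - max(h.ali_from, a.ali_from) + 1
            if shared > max_shared_aa:
                clash = True
                break
        if not clash:
            accepted.append(h)
    accepted.sort(key=lambda h: (h.ali_from, h.ali_to))
    segments = tuple(
        Segment(vocab.label(h.accession), h.ali_from, h.ali_to, h.bitscore)
        for h in accepted
    )
    arch = GeneArchitecture(gene_id=gene_id, segments=segments, role=ROLE_OTHER)
    return GeneArchitecture(gene_id=gene_id, segments=segments,
                            role=classify_gene_role(arch))


def classify_gene_role(arch: GeneArchitecture) -> str:
    """Deterministic role call from an architecture.

    Kinase roles: a Pkinase segment plus a CSD (resp. FHA) segment starting
    strictly after the kinase segment's end gives Pkinase_CSD (resp.
    Pkinase_FHA); a kinase with both C-terminal accessories is assigned by
    the higher-bitscore accessory and logged.  PP2C requires a PP2C segment
    and no Pkinase segment.  Psu yields the Psu role only in the absence of
    kinase/phosphatase segments.
    """
    segs = arch.segments
    kinases = [s for s in segs if s.label == "Pkinase"]
    pp2c = [s for s in segs if s.label == "PP2C"]
    psu = [s for s in segs if s.label == "Psu"]

    if kinases:
        kin_end = max(s.ali_to for s in kinases)
        csd = [s for s in segs if s.label == "CSD" and s.ali_from > kin_end]
        fha = [s for s in segs if s.label == "FHA" and s.ali_from > kin_end]
        if psu:
            log.warning("gene %s: Psu co-occurs with a kinase domain; "
                        "kinase role takes precedence", arch.gene_id)
        if csd and fha:
            best_csd = max(s.bitscore for s in csd)
            best_fha = max(s.bitscore for s in fha)
            log.warning("gene %s: both CSD and FHA C-terminal accessories; "
                        "assigning by higher bitscore", arch.gene_id)
            return ROLE_KINASE_CSD if best_csd >= best_fha else ROLE_KINASE_FHA
        if csd:
            return ROLE_KINASE_CSD
        if fha:
            return ROLE_KINASE_FHA
        return ROLE_KINASE_PLAIN
    if pp2c:
        if psu:
            log.warning("gene %s: Psu co-occurs with PP2C; PP2C takes "
                        "precedence", arch.gene_id)
        return ROLE_PP2C
    if psu:
        return ROLE_PSU
    return ROLE_OTHER


def architectures_for_genome(
    hits: list[DomainHit],
    gene_ids,
    vocab: DomainVocabulary | None = None,
    evalue_max: float = DEFAULT_EVALUE_MAX,
    max_shared_aa: int = DEFAULT_MAX_SHARED_AA,
) -> dict[str, GeneArchitecture]:
    """Build one architecture per gene id (empty architecture for genes
    without hits, which classify as role 'other')."""
    by_gene: dict[str, list[DomainHit]] = {}
    for h in hits:
        by_gene.setdefault(h.gene_id, []).append(h)
    archs: dict[str, GeneArchitecture] = {}
    for gid in gene_ids:
        archs[gid] = build_architecture(
            by_gene.get(gid, []), vocab=vocab, evalue_max=evalue_max,
            max_shared_aa=max_shared_aa, gene_id=gid,
        )
    return archs
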