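"""Seeded synthetic genomes with planted KKP clusters and typed decoys.

The generator emits, per genome, exactly the file dialects the pipeline
readers consume — GFF3 gene table, genome FASTA, HMMER3 per-domain hit
table, prophage BED, MGE TSV — plus one machine-readable truth table, so
every pipeline stage is testable without any download.

Planted items
-------------
* ``authentic`` — three consecutive same-strand genes whose roles read
  PP2C, kinase, kinase in transcription order, all 900-1300 bp, with one
  CSD-fused and one FHA-fused kinase; each carries an intended genomic
  context (prophage interval, nearby Psu gene, nearby MGE gene, or
  nothing).
* seven decoy classes, each violating exactly one scanner rule:
  ``WRONG_ORDER`` (kinase-phosphatase-kinase), ``MIXED_STRAND`` (middle
  gene flipped), ``NON_ADJACENT`` (an intervening unrelated CDS),
  ``KK_PAIR_ONLY`` (no phosphatase), ``LEN_OUT`` (one gene outside the
  900-1300 bp band), ``NO_CSD`` and ``NO_FHA`` (a plain kinase replacing
  the accessory-fused one).

The per-class expected scanner outcome is fixed in
:data:`DECOY_EXPECTATIONS`.

Background genes draw log-normal lengths, random strands, and mostly
``other`` roles, with a small rate of lone kinases and lone phosphatases
to create near-miss structure.  All randomness flows from one seed;
per-genome substreams are derived by counter, so extending a dataset never
perturbs earlier genomes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .model import (
    CTX_MGE,
    CTX_OTHER,
    CTX_P4,
    CTX_PROPHAGE,
    LEN_LONG,
    LEN_SHORT,
    MGE_CATEGORIES,
    NO_CSD,
    NO_FHA,
    ROLE_KINASE_CSD,
    ROLE_KINASE_FHA,
    ROLE_KINASE_PLAIN,
    ROLE_OTHER,
    ROLE_PP2C,
    ROLE_PSU,
)

DECOY_CLASSES = (
    "WRONG_ORDER", "MIXED_STRAND", "NON_ADJACENT", "LEN_OUT",
    "NO_CSD", "NO_FHA", "KK_PAIR_ONLY",
)

#: Expected scanner outcome per decoy class, fixed ahead of the scanner:
#: ``None`` — the class never forms a triplet candidate; otherwise the
#: exact rejection-code set the candidate must carry.
DECOY_EXPECTATIONS: dict[str, Optional[frozenset]] = {
    "WRONG_ORDER": None,
    "MIXED_STRAND": None,
    "NON_ADJACENT": None,
    "KK_PAIR_ONLY": None,
    "LEN_OUT": frozenset({LEN_SHORT, LEN_LONG}),  # one of these, per planted side
    "NO_CSD": frozenset({NO_CSD}),
    "NO_FHA": frozenset({NO_FHA}),
}

AA = "ACDEFGHIKLMNPQRSTVWY"

_BLOCK0 = 10          # CDS index of the first planted block
_BLOCK_SPACING = 35   # CDS indices between planted blocks
_PSU_OFFSET = 7       # Psu marker offset from the block start (P4 context)
_MGE_OFFSET = -2      # MGE gene offset from the block start (within 5 genes)


class ConfigError(ValueError):
    """The synthetic-data configuration is infeasible or invalid."""


@dataclass
class FamilyGroup:
    """A planned identity family: ``n_members`` clusters at pairwise
    ``identity`` (percent).  ``relative_to=(group_index, identity)`` derives
    this group's ancestor from an earlier group's at roughly that identity."""

    n_members: int
    identity: float
    relative_to: Optional[tuple[int, float]] = None


@dataclass
class SynthConfig:
    seed: int = 0
    n_genomes: int = 10
    genes_per_genome: int = 100
    gene_len_log_mean: float = math.log(950.0)
    gene_len_log_sd: float = 0.35
    intergenic_range: tuple[int, int] = (20, 200)
    n_authentic: int = 10
    decoy_counts: dict = field(
        default_factory=lambda: {c: 1 for c in DECOY_CLASSES})
    # context mix over authentic items; emulates the reported predominance
    # of temperate-phage locations (~90%) with ~60% of the remainder
    # MGE-linked
    context_mix: dict = field(default_factory=lambda: {
        CTX_PROPHAGE: 0.80, CTX_P4: 0.105, CTX_MGE: 0.058, CTX_OTHER: 0.037,
    })
    family_plan: Optional[list[FamilyGroup]] = None
    family_protein_len: int = 320
    background_role_rates: dict = field(default_factory=lambda: {
        ROLE_OTHER: 0.95, ROLE_KINASE_PLAIN: 0.03, ROLE_PP2C: 0.02,
    })
    taxa: tuple = ("Proteobacteria;Pseudomonas",
                   "Proteobacteria;Escherichia",
                   "Bacteroidetes;Bacteroides",
                   "Cyanobacteria;Synechococcus")
    n_trna_per_genome: int = 2

    def validate(self) -> None:
        if self.n_genomes < 1 or self.genes_per_genome < 30:
            raise ConfigError("need >=1 genome and >=30 genes per genome")
        bad = set(self.decoy_counts) - set(DECOY_CLASSES)
        if bad:
            raise ConfigError(f"unknown decoy classes: {sorted(bad)}")
        if abs(sum(self.context_mix.values()) - 1.0) > 1e-9:
            raise ConfigError("context_mix fractions must sum to 1")


@dataclass
class SynthDataset:
    """File layout of one generated dataset."""

    out_dir: Path
    genome_ids: list[str]
    truth: pd.DataFrame

    def gff(self, gid: str) -> Path: return self.out_dir / f"{gid}.gff"
    def fna(self, gid: str) -> Path: return self.out_dir / f"{gid}.fna"
    def domtbl(self, gid: str) -> Path: return self.out_dir / f"{gid}.domtbl"
    def bed(self, gid: str) -> Path: return self.out_dir / f"{gid}_prophage.bed"
    def mge(self, gid: str) -> Path: return self.out_dir / f"{gid}_mge.tsv"
    @property
    def proteins(self) -> Path: return self.out_dir / "proteins.faa"
    @property
    def truth_path(self) -> Path: return self.out_dir / "truth.tsv"


# ---------------------------------------------------------------------------
# identity-family planting


def plant_identity_family(
    rng: np.random.Generator,
    n_members: int,
    target_identity: float,
    length: int = 320,
    ancestor: Optional[str] = None,
) -> list[str]:
    """Mutate one ancestor into ``n_members`` sequences whose realized
    gapless pairwise identity is within +-1 point of ``target_identity``.

    Each member substitutes a disjoint set of positions, so any two members
    differ at exactly the union of their two sets: with per-member set
    sizes alternating floor(k/2) / ceil(k/2) for k = L*(1 - t/100), every
    pairwise identity lands within one substitution of the target.
    """
    if not 0 < target_identity <= 100:
        raise ConfigError("target identity must be in (0, 100]")
    if ancestor is None:
        ancestor = "".join(rng.choice(list(AA), size=length))
    length = len(ancestor)
    k = length * (100.0 - target_identity) / 100.0
    lo = int(math.floor(k / 2.0 + 1e-9))
    hi = int(math.ceil(k / 2.0 - 1e-9))
    sizes = [lo if i % 2 == 0 else hi for i in range(n_members)]
    if sum(sizes) > length:
        raise ConfigError(
            f"cannot plant {n_members} members at {target_identity}% "
            f"identity on {length} aa: not enough disjoint positions"
        )
    positions = rng.permutation(length)
    members = []
    cursor = 0
    for size in sizes:
        seq = list(ancestor)
        for pos in positions[cursor:cursor + size]:
            choices = [c for c in AA if c != seq[pos]]
            seq[pos] = choices[rng.integers(len(choices))]
        cursor += size
        members.append("".join(seq))
    return members


def _mutate(rng: np.random.Generator, seq: str, identity: float) -> str:
    """One derived sequence at roughly ``identity``% to ``seq`` (gapless)."""
    n_sub = int(round(len(seq) * (100.0 - identity) / 100.0))
    out = list(seq)
    for pos in rng.choice(len(seq), size=n_sub, replace=False):
        choices = [c for c in AA if c != out[pos]]
        out[pos] = choices[rng.integers(len(choices))]
    return "".join(out)


# ---------------------------------------------------------------------------
# planted-item plans


@dataclass
class _Item:
    item_id: str
    klass: str                      # 'authentic' or a decoy class
    context: str = CTX_OTHER        # intended category (authentic only)
    family_id: str = ""
    family_group: Optional[int] = None
    family_member: Optional[int] = None


def _context_counts(mix: dict, n: int) -> dict:
    """Largest-remainder apportionment of n items over the mix fractions."""
    cats = list(mix)
    raw = {c: mix[c] * n for c in cats}
    counts = {c: int(math.floor(raw[c])) for c in cats}
    rem = n - sum(counts.values())
    order = sorted(cats, key=lambda c: (-(raw[c] - counts[c]), cats.index(c)))
    for c in order[:rem]:
        counts[c] += 1
    return counts


def _build_item_queue(config: SynthConfig) -> list[_Item]:
    items: list[_Item] = []
    ctx_counts = _context_counts(config.context_mix, config.n_authentic)
    contexts = []
    # interleave contexts so every genome sees a representative mix
    pools = {c: ctx_counts[c] for c in ctx_counts}
    order = (CTX_PROPHAGE, CTX_P4, CTX_MGE, CTX_OTHER)
    while any(pools.values()):
        for c in order:
            if pools.get(c, 0) > 0:
                contexts.append(c)
                pools[c] -= 1
    plan_assign: list[tuple[str, int, int]] = []
    if config.family_plan:
        for gi, group in enumerate(config.family_plan):
            for mi in range(group.n_members):
                plan_assign.append((f"FP{gi:02d}", gi, mi))
        if len(plan_assign) > config.n_authentic:
            raise ConfigError("family plan larger than n_authentic")
    for i in range(config.n_authentic):
        fam = plan_assign[i] if i < len(plan_assign) else (f"FU{i:04d}", None, None)
        items.append(_Item(
            item_id=f"A{i:04d}", klass="authentic", context=contexts[i],
            family_id=fam[0], family_group=fam[1], family_member=fam[2],
        ))
    di = 0
    for klass in DECOY_CLASSES:
        for _ in range(int(config.decoy_counts.get(klass, 0))):
            items.append(_Item(item_id=f"D{di:04d}", klass=klass))
            di += 1
    return items


def _family_proteins(config: SynthConfig, rng: np.random.Generator,
                     items: list[_Item]) -> dict[tuple[int, int], dict[str, str]]:
    """(group, member) -> {component -> protein} for the family plan."""
    if not config.family_plan:
        return {}
    out: dict[tuple[int, int], dict[str, str]] = {}
    ancestors: dict[int, dict[str, str]] = {}
    for gi, group in enumerate(config.family_plan):
        comp_anc = {}
        for comp in ("pfkA", "pfkB", "pfpC"):
            if group.relative_to is not None:
                base_gi, rel_ident = group.relative_to
                if base_gi not in ancestors:
                    raise ConfigError(
                        f"group {gi} relative_to unknown group {base_gi}")
                comp_anc[comp] = _mutate(rng, ancestors[base_gi][comp],
                                         rel_ident)
            else:
                comp_anc[comp] = "".join(
                    rng.choice(list(AA), size=config.family_protein_len))
        ancestors[gi] = comp_anc
        per_comp = {
            comp: plant_identity_family(
                rng, group.n_members, group.identity,
                ancestor=comp_anc[comp])
            for comp in ("pfkA", "pfkB", "pfpC")
        }
        for mi in range(group.n_members):
            out[(gi, mi)] = {comp: per_comp[comp][mi]
                             for comp in ("pfkA", "pfkB", "pfpC")}
    return out


# ---------------------------------------------------------------------------
# per-genome synthesis


def _block_width(klass: str) -> int:
    return {"NON_ADJACENT": 4, "KK_PAIR_ONLY": 2}.get(klass, 3)


def _genome_capacity(n_genes: int) -> int:
    cap = 0
    start = _BLOCK0
    while start + 4 + _PSU_OFFSET < n_genes - 2:
        cap += 1
        start += _BLOCK_SPACING
    return cap


def _roles_for_item(item: _Item, rng: np.random.Generator):
    """Transcription-order roles, strand pattern, and per-gene lengths."""
    kin = [ROLE_KINASE_CSD, ROLE_KINASE_FHA]
    rng.shuffle(kin)
    strand = "+" if rng.random() < 0.5 else "-"
    lengths = list(rng.integers(950, 1270, size=_block_width(item.klass)))
    expected_reason = ""
    if item.klass in ("authentic", "MIXED_STRAND"):
        roles = [ROLE_PP2C, kin[0], kin[1]]
    elif item.klass == "WRONG_ORDER":
        roles = [kin[0], ROLE_PP2C, kin[1]]
    elif item.klass == "NON_ADJACENT":
        roles = [ROLE_PP2C, kin[0], ROLE_OTHER, kin[1]]
    elif item.klass == "KK_PAIR_ONLY":
        roles = [kin[0], kin[1]]
    elif item.klass == "LEN_OUT":
        roles = [ROLE_PP2C, kin[0], kin[1]]
        which = int(rng.integers(3))
        if rng.random() < 0.5:
            lengths[which] = int(rng.integers(750, 880))
            expected_reason = LEN_SHORT
        else:
            lengths[which] = int(rng.integers(1330, 1450))
            expected_reason = LEN_LONG
    elif item.klass == "NO_CSD":
        roles = [ROLE_PP2C, ROLE_KINASE_PLAIN, ROLE_KINASE_FHA]
        rngswap = rng.random() < 0.5
        if rngswap:
            roles = [ROLE_PP2C, ROLE_KINASE_FHA, ROLE_KINASE_PLAIN]
        expected_reason = NO_CSD
    elif item.klass == "NO_FHA":
        roles = [ROLE_PP2C, ROLE_KINASE_CSD, ROLE_KINASE_PLAIN]
        if rng.random() < 0.5:
            roles = [ROLE_PP2C, ROLE_KINASE_PLAIN, ROLE_KINASE_CSD]
        expected_reason = NO_FHA
    else:
        raise ConfigError(f"unknown item class {item.klass}")
    strands = [strand] * len(roles)
    if item.klass == "MIXED_STRAND":
        strands[1] = "-" if strand == "+" else "+"
    return roles, strands, lengths, expected_reason


def _domain_hits_for_role(gene_id: str, role: str, protein_len: int,
                          rng: np.random.Generator) -> list[tuple]:
    """(accession, name, i_evalue, bitscore, ali_from, ali_to) rows."""
    rows = []

    def hit(acc, name, frm, to, bits_lo, bits_hi, exp_lo=25, exp_hi=60):
        to = min(to, protein_len - 2)
        if to <= frm:
            return
        bits = float(np.round(rng.uniform(bits_lo, bits_hi), 1))
        ev = 10.0 ** float(-rng.uniform(exp_lo, exp_hi))
        rows.append((acc, name, ev, bits, frm, to))

    # domain layout scales with protein length so C-terminal accessory
    # domains still fit on short (out-of-band) planted genes
    kin_to = min(260, int(protein_len * 0.72))
    acc_from = kin_to + 10
    acc_to = min(acc_from + 68, protein_len - 2)
    if role in (ROLE_KINASE_CSD, ROLE_KINASE_FHA, ROLE_KINASE_PLAIN):
        hit("PF00069", "Pkinase", 5, kin_to, 150, 280)
    if role == ROLE_KINASE_CSD:
        hit("PF00313", "CSD", acc_from, acc_to, 45, 90)
    if role == ROLE_KINASE_FHA:
        hit("PF00498", "FHA", acc_from, acc_to, 45, 90)
    if role == ROLE_PP2C:
        hit("PF13672", "PP2C", 10, min(245, protein_len - 10), 120, 240)
    if role == ROLE_PSU:
        hit("PF07455", "Psu", 5, 170, 80, 150)
    return rows


DOMTBL_HEADER = (
    "#                                                               "
    "--- full sequence --- -------------- this domain -------------   "
    "hmm coord   ali coord   env coord\n"
    "# target name        accession   tlen query name           "
    "accession   qlen   E-value  score  bias   #  of  c-Evalue  "
    "i-Evalue  score  bias  from    to  from    to  from    to  acc "
    "description of target\n"
)


def _random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AA), size=length))


def generate_dataset(config: SynthConfig, out_dir) -> SynthDataset:
    """Write a full synthetic dataset and its truth table to ``out_dir``."""
    config.validate()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    root_rng = np.random.default_rng(np.random.SeedSequence(config.seed))

    items = _build_item_queue(config)
    fam_proteins = _family_proteins(config, root_rng, items)

    # per-genome gene counts and item assignment (capacity-ordered fill)
    genome_ids = [f"G{g:04d}" for g in range(config.n_genomes)]
    sizes = {}
    capacities = {}
    for g, gid in enumerate(genome_ids):
        sub = np.random.default_rng(
            np.random.SeedSequence(config.seed, spawn_key=(g,)))
        n_genes = max(30, int(round(sub.normal(config.genes_per_genome, 8))))
        sizes[gid] = n_genes
        capacities[gid] = _genome_capacity(n_genes)
    total_cap = sum(capacities.values())
    if len(items) > total_cap:
        raise ConfigError(
            f"{len(items)} planted items exceed capacity {total_cap} "
            f"({config.n_genomes} genomes x ~{capacities[genome_ids[0]]})"
        )
    assignment: dict[str, list[_Item]] = {gid: [] for gid in genome_ids}
    queue = list(items)
    for gid in genome_ids:
        while queue and len(assignment[gid]) < capacities[gid]:
            assignment[gid].append(queue.pop(0))

    truth_rows = []
    protein_records: dict[str, str] = {}
    for g, gid in enumerate(genome_ids):
        rng = np.random.default_rng(
            np.random.SeedSequence(config.seed, spawn_key=(g, 1)))
        rows = _synthesize_genome(
            config, gid, g, sizes[gid], assignment[gid], rng,
            fam_proteins, protein_records, out_dir,
        )
        truth_rows.extend(rows)

    truth = pd.DataFrame(truth_rows, columns=[
        "item_id", "klass", "genome_id", "contig_id", "cds_indices",
        "gene_ids", "strand", "pattern", "context", "family_id",
        "expected_reason", "forms_candidate",
    ])
    truth.to_csv(out_dir / "truth.tsv", sep="\t", index=False)
    with open(out_dir / "proteins.faa", "w") as fh:
        for name in protein_records:
            fh.write(f">{name}\n{protein_records[name]}\n")
    return SynthDataset(out_dir=out_dir, genome_ids=genome_ids, truth=truth)


def _synthesize_genome(config: SynthConfig, gid: str, g_index: int,
                       n_genes: int, g_items: list, rng: np.random.Generator,
                       fam_proteins: dict, protein_records: dict,
                       out_dir: Path) -> list[dict]:
    contig = f"{gid}_c1"
    taxon = config.taxa[g_index % len(config.taxa)]

    # CDS slot plan: role/strand/length per slot, then a coordinate walk
    roles = []
    strands = []
    lengths = []
    bg_rates = config.background_role_rates
    bg_roles = list(bg_rates)
    bg_p = np.array([bg_rates[r] for r in bg_roles], dtype=float)
    bg_p = bg_p / bg_p.sum()
    for _ in range(n_genes):
        roles.append(bg_roles[int(rng.choice(len(bg_roles), p=bg_p))])
        strands.append("+" if rng.random() < 0.5 else "-")
        lengths.append(max(150, int(rng.lognormal(
            config.gene_len_log_mean, config.gene_len_log_sd))))

    item_blocks = []  # (item, block_start, roles_tx, strands, lengths, reason)
    start = _BLOCK0
    for item in g_items:
        roles_tx, item_strands, item_lengths, reason = _roles_for_item(item, rng)
        item_blocks.append((item, start, roles_tx, item_strands,
                            item_lengths, reason))
        start += _BLOCK_SPACING

    psu_slots = {}
    mge_slots = {}
    for item, bstart, roles_tx, item_strands, item_lengths, _ in item_blocks:
        width = len(roles_tx)
        # transcription order -> coordinate order
        if item_strands[0] == "+":
            coord_roles = roles_tx
        else:
            coord_roles = roles_tx[::-1]
        for off, role in enumerate(coord_roles):
            roles[bstart + off] = role
            strands[bstart + off] = item_strands[off]
            lengths[bstart + off] = (item_lengths[off] if item_strands[0] == "+"
                                     else item_lengths[::-1][off])
        # buffer genes around the block never carry a scan-relevant role
        for off in range(-2, width + 2):
            idx = bstart + off
            if 0 <= idx < n_genes and not (0 <= off < width):
                roles[idx] = ROLE_OTHER
        if item.klass == "authentic":
            if item.context == CTX_P4:
                psu_slots[bstart + _PSU_OFFSET] = item.item_id
            elif item.context == CTX_MGE:
                mge_slots[bstart + _MGE_OFFSET] = item.item_id
    for slot in psu_slots:
        roles[slot] = ROLE_PSU
        lengths[slot] = max(lengths[slot], 600)

    # coordinate walk; tRNAs inserted away from planted blocks
    blocked = set()
    for _, bstart, roles_tx, _, _, _ in item_blocks:
        blocked.update(range(bstart - 3, bstart + len(roles_tx) + 3))
    trna_slots = set()
    for cand in (5, n_genes - 5):
        if cand not in blocked and len(trna_slots) < config.n_trna_per_genome:
            trna_slots.add(cand)

    gff_rows = []
    gene_meta = []  # (gene_id, role, length, protein_len)
    pos = 1
    lo_gap, hi_gap = config.intergenic_range
    for i in range(n_genes):
        if i in trna_slots:
            t_start = pos + 10
            t_end = t_start + 74
            gff_rows.append((contig, "synth", "tRNA", t_start, t_end, ".",
                             "+", ".", f"ID={gid}_t{i:05d};product=tRNA-Xxx"))
            pos = t_end + 1 + int(rng.integers(lo_gap, hi_gap))
        gstart = pos + int(rng.integers(lo_gap, hi_gap))
        gend = gstart + lengths[i] - 1
        gene_id = f"{gid}_g{i:05d}"
        gff_rows.append((contig, "synth", "CDS", gstart, gend, ".",
                         strands[i], "0", f"ID={gene_id}"))
        protein_len = max(50, (lengths[i] - 3) // 3)
        gene_meta.append((gene_id, roles[i], lengths[i], protein_len))
        pos = gend + 1

    contig_len = pos + 200
    seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=contig_len)])

    # domain-hit table
    domtbl_lines = []
    for gene_id, role, _, protein_len in gene_meta:
        rows = _domain_hits_for_role(gene_id, role, protein_len, rng)
        if role == ROLE_OTHER:
            r = rng.random()
            if r < 0.05:  # uninformative hit outside the vocabulary
                rows.append(("PF12345", "DUF9999",
                             10.0 ** float(-rng.uniform(8, 20)),
                             float(np.round(rng.uniform(30, 80), 1)),
                             5, min(120, protein_len - 2)))
            elif r < 0.07:  # weak kinase hit above the E-value cutoff
                rows.append(("PF00069", "Pkinase", 10.0 ** float(-rng.uniform(1, 4)),
                             float(np.round(rng.uniform(8, 14), 1)),
                             5, min(120, protein_len - 2)))
        for acc, name, ev, bits, frm, to in rows:
            domtbl_lines.append(
                f"{gene_id:<20s} -          {protein_len:5d} "
                f"{name:<20s} {acc:<11s} {to - frm + 1:5d} "
                f"{ev:9.2g} {bits:6.1f}   0.0   1   1 {ev:9.2g} {ev:9.2g} "
                f"{bits:6.1f}   0.0     1 {to - frm + 1:5d} {frm:5d} {to:5d} "
                f"{max(1, frm - 2):5d} {min(protein_len, to + 2):5d} 0.95 -"
            )

    # context artifacts + truth rows
    bed_lines = []
    mge_lines = []
    truth_rows = []
    by_index = {i: gff for i, gff in enumerate(
        r for r in gff_rows if r[2] == "CDS")}
    for item, bstart, roles_tx, item_strands, item_lengths, reason in item_blocks:
        width = len(roles_tx)
        idxs = list(range(bstart, bstart + width))
        gene_ids = [gene_meta[i][0] for i in idxs]
        span_start = by_index[idxs[0]][3]
        span_end = by_index[idxs[-1]][4]
        if item.klass == "authentic" and item.context == CTX_PROPHAGE:
            pad_l = int(rng.integers(500, 2500))
            pad_r = int(rng.integers(500, 2500))
            bstart_bed = max(0, span_start - pad_l - 1)  # BED is 0-based
            bed_lines.append(
                f"{contig}\t{bstart_bed}\t{span_end + pad_r}\tprophage")
        if item.klass == "authentic" and item.context == CTX_MGE:
            slot = bstart + _MGE_OFFSET
            cat = MGE_CATEGORIES[int(rng.integers(len(MGE_CATEGORIES)))]
            mge_lines.append(f"{gene_meta[slot][0]}\t{cat}")
        # proteins for authentic cluster components
        if item.klass == "authentic":
            comp_by_role = {ROLE_KINASE_CSD: "pfkA", ROLE_KINASE_FHA: "pfkB",
                            ROLE_PP2C: "pfpC"}
            planned = (fam_proteins.get((item.family_group, item.family_member))
                       if item.family_group is not None else None)
            tx_gene_ids = gene_ids if item_strands[0] == "+" else gene_ids[::-1]
            for role, gid_tx in zip(roles_tx, tx_gene_ids):
                comp = comp_by_role[role]
                if planned is not None:
                    prot = planned[comp]
                else:
                    meta = next(m for m in gene_meta if m[0] == gid_tx)
                    prot = _random_protein(rng, meta[3])
                protein_records[f"{item.item_id}|{comp}|{gid_tx}"] = prot
        truth_rows.append({
            "item_id": item.item_id,
            "klass": item.klass,
            "genome_id": gid,
            "contig_id": contig,
            "cds_indices": ",".join(str(i) for i in idxs),
            "gene_ids": ",".join(gene_ids),
            "strand": item_strands[0],
            "pattern": "PKK",
            "context": item.context if item.klass == "authentic" else CTX_OTHER,
            "family_id": item.family_id,
            "expected_reason": reason,
            "forms_candidate":
                str(DECOY_EXPECTATIONS.get(item.klass, frozenset())
                    is not None),
        })

    # write files (tRNA/CDS rows are already in coordinate order)
    with open(out_dir / f"{gid}.gff", "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {contig} 1 {contig_len}\n")
        fh.write(f"# taxon: {taxon}\n")
        for row in gff_rows:
            fh.write("\t".join(str(x) for x in row) + "\n")
    with open(out_dir / f"{gid}.fna", "w") as fh:
        fh.write(f">{contig}\n")
        for i in range(0, contig_len, 70):
            fh.write(seq[i:i + 70] + "\n")
    with open(out_dir / f"{gid}.domtbl", "w") as fh:
        fh.write(DOMTBL_HEADER)
        fh.write("\n".join(domtbl_lines) + ("\n" if domtbl_lines else ""))
    with open(out_dir / f"{gid}_prophage.bed", "w") as fh:
        fh.write("\n".join(bed_lines) + ("\n" if bed_lines else ""))
    with open(out_dir / f"{gid}_mge.tsv", "w") as fh:
        fh.write("\n".join(mge_lines) + ("\n" if mge_lines else ""))
    return truth_rows


# ---------------------------------------------------------------------------
# loading a generated dataset back through the production readers


def load_genome(dataset: SynthDataset, gid: str, evalue_max: float = 1e-5):
    """Read one synthetic genome back with the production readers; returns
    (GenomeTable, architectures, intervals, mge_table)."""
    from .domain_arch import architectures_for_genome, read_domain_hits
    from .genome_io import read_gene_table, read_intervals, read_mge_table

    table = read_gene_table(dataset.gff(gid), gid, fmt="gff3")
    hits = read_domain_hits(dataset.domtbl(gid))
    archs = architectures_for_genome(
        hits, [g.gene_id for g in table.genes() if g.ftype == "CDS"],
        evalue_max=evalue_max)
    bed = dataset.bed(gid)
    intervals = (read_intervals(bed, dialect="bed")
                 if bed.stat().st_size > 0 else [])
    mge_path = dataset.mge(gid)
    mge = read_mge_table(mge_path, table) if mge_path.stat().st_size > 0 else {}
    return table, archs, intervals, mge


def load_planted_proteins(dataset: SynthDataset) -> dict[str, dict[str, str]]:
    """item_id -> {component -> protein sequence} from proteins.faa."""
    from .genome_io import read_fasta

    out: dict[str, dict[str, str]] = {}
    for name, seq in read_fasta(dataset.proteins).items():
        item_id, comp, _gene = name.split("|")
        out.setdefault(item_id, {})[comp] = seq
    return out
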