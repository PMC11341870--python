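"""Independent oracles used by the test suite.

These deliberately re-derive expected results by brute force or via a
third-party implementation, and never call the code paths they check.
"""

from __future__ import annotations

import itertools

KINASES = {"Pkinase_CSD", "Pkinase_FHA", "Pkinase_plain"}


def brute_force_clusters(table, archs, min_bp=900, max_bp=1300,
                         pattern="both"):
    """Exhaustive window oracle: test every (i, i+1, i+2) CDS window on
    every contig against the triplet rules, written independently of the
    scanner.  Returns a set of (contig, index_triple, status, reasons)."""
    found = set()
    for contig_id, genes in table.contigs.items():
        cds = [g for g in genes if g.ftype == "CDS"]
        for i in range(len(cds) - 2):
            w = cds[i], cds[i + 1], cds[i + 2]
            strands = {g.strand for g in w}
            if len(strands) != 1:
                continue
            strand = strands.pop()
            roles = [archs[g.gene_id].role for g in w]
            tx = roles if strand == "+" else list(reversed(roles))
            is_pkk = (tx[0] == "PP2C" and tx[1] in KINASES and tx[2] in KINASES)
            is_kkp = (tx[2] == "PP2C" and tx[0] in KINASES and tx[1] in KINASES)
            ok = (is_pkk and pattern in ("PKK", "both")) or \
                 (is_kkp and pattern in ("KKP", "both"))
            if not ok:
                continue
            reasons = set()
            for g in w:
                if g.length_bp <= min_bp:
                    reasons.add("LEN_SHORT")
                if g.length_bp >= max_bp:
                    reasons.add("LEN_LONG")
            kin_roles = [r for r in roles if r in KINASES]
            if kin_roles.count("Pkinase_CSD") == 0:
                reasons.add("NO_CSD")
            if kin_roles.count("Pkinase_FHA") == 0:
                reasons.add("NO_FHA")
            if (kin_roles.count("Pkinase_CSD") > 1
                    or kin_roles.count("Pkinase_FHA") > 1):
                reasons.add("DUP_ACCESSORY")
            status = "authentic" if not reasons else "rejected"
            found.add((contig_id, tuple(g.index for g in w), status,
                       frozenset(reasons)))
    return found


def clusters_to_oracle_set(clusters):
    """Project scanner output onto the oracle's comparison tuple."""
    return {
        (c.candidate.contig_id, c.candidate.index_triple, c.status,
         frozenset(c.report.reasons))
        for c in clusters
    }


def enumerate_global_alignments(a, b, score_fn, gap_open, gap_extend):
    """Exhaustive recursion over every global alignment of two short
    sequences under affine gap costs (gap of length L costs
    gap_open + L * gap_extend); returns the optimal score."""
    best = [float("-inf")]

    def rec(i, j, score, last):
        if i == len(a) and j == len(b):
            best[0] = max(best[0], score)
            return
        if i < len(a) and j < len(b):
            rec(i + 1, j + 1, score + score_fn(a[i], b[j]), "M")
        if i < len(a):  # gap in b
            cost = gap_extend if last == "D" else gap_open + gap_extend
            rec(i + 1, j, score + cost, "D")
        if j < len(b):  # gap in a
            cost = gap_extend if last == "I" else gap_open + gap_extend
            rec(i, j + 1, score + cost, "I")

    rec(0, 0, 0.0, None)
    return best[0]


def biopython_global_score(a, b, match=1.0, mismatch=-2.0,
                           gap_open=-5.0, gap_extend=-1.0):
    """Independent affine global alignment score via Bio.Align."""
    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap_open + gap_extend
    aligner.extend_gap_score = gap_extend
    return aligner.score(a, b)


def connected_components_families(pairs, members):
    """Independent single-linkage oracle via networkx connected components;
    ``pairs`` is an iterable of (a, b) edges above the threshold."""
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(members)
    g.add_edges_from(pairs)
    return {frozenset(c) for c in nx.connected_components(g)}


def reverse_complement_table(table):
    """Mirror a GenomeTable: flip coordinates, strands, and gene order, as
    if the contig had been reverse-complemented."""
    from kkpscan.model import GeneRecord, GenomeTable

    out = GenomeTable(table.genome_id + "_rc", taxon=table.taxon)
    for contig_id, genes in table.contigs.items():
        length = max(g.end for g in genes) + 100
        for g in genes:
            out.add(GeneRecord(
                gene_id=g.gene_id,
                contig_id=contig_id,
                start=length - g.end + 1,
                end=length - g.start + 1,
                strand="-" if g.strand == "+" else "+",
                ftype=g.ftype,
                protein_len_aa=g.protein_len_aa,
                product=g.product,
            ))
    return out.finalize()


def all_orderings(items):
    return list(itertools.permutations(items))
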