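from __future__ import annotations

import pytest

from helpers import (
    brute_force_clusters,
    clusters_to_oracle_set,
    reverse_complement_table,
)
from kkpscan.kkp_scan import (
    apply_architecture_filter,
    apply_length_filter,
    authentic_fraction,
    classify_clusters,
    scan_triplets,
)
from kkpscan.model import GeneArchitecture, GeneRecord, GenomeTable
from kkpscan.simulate import load_genome


def make_genome(roles, strands=None, lengths=None, contig="c1"):
    """Build a GenomeTable + architecture dict from a role list."""
    n = len(roles)
    strands = strands or ["+"] * n
    lengths = lengths or [1000] * n
    t = GenomeTable("G")
    archs = {}
    pos = 1
    for i, role in enumerate(roles):
        gid = f"g{i}"
        t.add(GeneRecord(gid, contig, pos, pos + lengths[i] - 1, strands[i]))
        archs[gid] = GeneArchitecture(gene_id=gid, segments=(), role=role)
        pos += lengths[i] + 100
    return t.finalize(), archs


AUTH = ["other", "PP2C", "Pkinase_CSD", "Pkinase_FHA", "other"]


class TestScanTriplets:
    def test_plus_strand_pkk_match(self):
        t, a = make_genome(AUTH)
        (cand,) = scan_triplets(t, a)
        assert cand.roles == ("PP2C", "Pkinase_CSD", "Pkinase_FHA")
        assert cand.pattern == "PKK"

    def test_flipped_middle_gene_kills_candidate(self):
        t, a = make_genome(AUTH, strands=["+", "+", "-", "+", "+"])
        assert scan_triplets(t, a) == []

    def test_minus_strand_reads_in_transcription_order(self):
        # coordinate order K_FHA, K_CSD, PP2C on '-' is P-K-K transcribed
        t, a = make_genome(["Pkinase_FHA", "Pkinase_CSD", "PP2C"],
                           strands=["-"] * 3)
        (cand,) = scan_triplets(t, a, pattern="PKK")
        assert cand.roles[0] == "PP2C"
        assert [g.gene_id for g in cand.genes] == ["g2", "g1", "g0"]

    def test_intervening_gene_breaks_adjacency(self):
        t, a = make_genome(["PP2C", "Pkinase_CSD", "other", "Pkinase_FHA"])
        assert scan_triplets(t, a) == []

    def test_trna_between_genes_does_not_break_adjacency(self):
        t = GenomeTable("G")
        archs = {}
        layout = [("g0", "CDS", "PP2C"), ("t0", "tRNA", None),
                  ("g1", "CDS", "Pkinase_CSD"), ("g2", "CDS", "Pkinase_FHA")]
        pos = 1
        for gid, ftype, role in layout:
            glen = 1000 if ftype == "CDS" else 75
            t.add(GeneRecord(gid, "c1", pos, pos + glen - 1, "+", ftype=ftype))
            if role:
                archs[gid] = GeneArchitecture(gene_id=gid, segments=(),
                                              role=role)
            pos += glen + 50
        (cand,) = scan_triplets(t.finalize(), archs)
        assert [g.gene_id for g in cand.genes] == ["g0", "g1", "g2"]

    def test_kkp_transcription_order_matches_under_both(self):
        t, a = make_genome(["Pkinase_CSD", "Pkinase_FHA", "PP2C"])
        (cand,) = scan_triplets(t, a, pattern="both")
        assert cand.pattern == "KKP"
        assert scan_triplets(t, a, pattern="PKK") == []

    def test_missing_architecture_names_gene(self):
        t, a = make_genome(AUTH)
        del a["g2"]
        with pytest.raises(KeyError, match="g2"):
            scan_triplets(t, a)


class TestLengthFilter:
    def _cand(self, lengths):
        t, a = make_genome(AUTH[1:4], lengths=lengths)
        (cand,) = scan_triplets(t, a)
        return cand

    def test_in_band_passes(self):
        rep = apply_length_filter(self._cand([1000, 1100, 1200]))
        assert rep.accepted and rep.length_pass == (True, True, True)

    def test_exactly_900_fails_short(self):
        rep = apply_length_filter(self._cand([900, 1000, 1000]))
        assert rep.reasons == ["LEN_SHORT"]

    def test_exactly_1300_fails_long(self):
        rep = apply_length_filter(self._cand([1000, 1300, 1000]))
        assert rep.reasons == ["LEN_LONG"]

    def test_bad_bounds_rejected(self):
        with pytest.raises(ValueError):
            apply_length_filter(self._cand([1000] * 3), min_bp=1300, max_bp=900)

    def test_widening_bounds_never_loses_authentic(self, small_dataset):
        counts = []
        for lo, hi in [(950, 1250), (900, 1300), (700, 1600)]:
            n = 0
            for gid in small_dataset.genome_ids:
                table, archs, _, _ = load_genome(small_dataset, gid)
                n += sum(c.status == "authentic" for c in
                         classify_clusters(table, archs, min_bp=lo, max_bp=hi))
            counts.append(n)
        assert counts == sorted(counts)


class TestArchitectureFilter:
    @pytest.mark.parametrize("k1,k2,reasons", [
        ("Pkinase_CSD", "Pkinase_FHA", []),
        ("Pkinase_FHA", "Pkinase_CSD", []),  # position-free accessory pairing
        ("Pkinase_plain", "Pkinase_FHA", ["NO_CSD"]),
        ("Pkinase_CSD", "Pkinase_plain", ["NO_FHA"]),
        ("Pkinase_CSD", "Pkinase_CSD", ["NO_FHA", "DUP_ACCESSORY"]),
        ("Pkinase_FHA", "Pkinase_FHA", ["NO_CSD", "DUP_ACCESSORY"]),
        ("Pkinase_plain", "Pkinase_plain", ["NO_CSD", "NO_FHA"]),
    ])
    def test_accessory_pairing(self, k1, k2, reasons):
        t, a = make_genome(["PP2C", k1, k2])
        (cand,) = scan_triplets(t, a)
        rep = apply_architecture_filter(cand)
        assert rep.reasons == reasons


class TestClassifyClusters:
    def test_component_gene_assignment(self):
        t, a = make_genome(AUTH)
        (c,) = classify_clusters(t, a)
        assert c.status == "authentic"
        assert (c.pfpC_like, c.pfkA_like, c.pfkB_like) == ("g1", "g2", "g3")

    def test_no_phosphatase_no_clusters(self):
        t, a = make_genome(["Pkinase_CSD", "Pkinase_FHA", "other"])
        assert classify_clusters(t, a) == []

    def test_every_candidate_authentic_or_reasoned(self, small_dataset):
        for gid in small_dataset.genome_ids:
            table, archs, _, _ = load_genome(small_dataset, gid)
            for c in classify_clusters(table, archs):
                assert (c.status == "authentic") == (not c.report.reasons)

    @pytest.mark.parametrize("seed", range(6))
    def test_equals_brute_force_window_oracle(self, seed, dataset_factory):
        ds = dataset_factory(seed=100 + seed, n_genomes=6,
                             genes_per_genome=100, n_authentic=6)
        for gid in ds.genome_ids:
            table, archs, _, _ = load_genome(ds, gid)
            got = clusters_to_oracle_set(classify_clusters(table, archs))
            want = brute_force_clusters(table, archs)
            assert got == want

    def test_strand_mirror_bijection(self, small_dataset):
        """Reverse-complementing a genome preserves the cluster set."""
        for gid in small_dataset.genome_ids:
            table, archs, _, _ = load_genome(small_dataset, gid)
            mirrored = reverse_complement_table(table)
            fwd = {(frozenset(g.gene_id for g in c.candidate.genes),
                    c.status, frozenset(c.report.reasons))
                   for c in classify_clusters(table, archs)}
            rev = {(frozenset(g.gene_id for g in c.candidate.genes),
                    c.status, frozenset(c.report.reasons))
                   for c in classify_clusters(mirrored, archs)}
            assert fwd == rev


class TestAuthenticFraction:
    def test_ratio(self):
        t, a = make_genome(AUTH)
        clusters = classify_clusters(t, a)
        assert authentic_fraction(clusters) == pytest.approx(100.0)

    def test_mixed(self):
        auth, _ = [], None
        t, a = make_genome(
            ["PP2C", "Pkinase_CSD", "Pkinase_FHA", "other",
             "PP2C", "Pkinase_CSD", "Pkinase_CSD", "other"])
        clusters = classify_clusters(t, a)
        assert len(clusters) == 2
        assert authentic_fraction(clusters) == pytest.approx(50.0)

    def test_empty_is_undefined_not_zero(self):
        assert authentic_fraction([]) is None
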