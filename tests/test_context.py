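from __future__ import annotations

import itertools

import pytest

from kkpscan.context import (
    annotate_contexts,
    assign_context,
    mge_linked,
    overlaps_prophage,
    rescue_p4,
    summarize_contexts,
)
from kkpscan.kkp_scan import classify_clusters
from kkpscan.model import (
    ContextAnnotation,
    Evidence,
    GeneArchitecture,
    GeneRecord,
    GenomeTable,
    Interval,
)
from kkpscan.simulate import load_genome
from test_kkp_scan import AUTH, make_genome


def _cluster(start=10_000, glen=1100, contig="c1", extra_roles=(),
             n_lead=0):
    """A genome with one authentic cluster starting near ``start`` plus
    optional surrounding genes; returns (cluster, table, archs)."""
    roles = list(extra_roles[:n_lead]) + ["PP2C", "Pkinase_CSD",
                                          "Pkinase_FHA"] + \
        list(extra_roles[n_lead:])
    t = GenomeTable("G")
    archs = {}
    pos = start
    # genes before `start` if any leading extras
    pos = start - n_lead * (glen + 100)
    for i, role in enumerate(roles):
        gid = f"g{i}"
        t.add(GeneRecord(gid, contig, pos, pos + glen - 1, "+"))
        archs[gid] = GeneArchitecture(gene_id=gid, segments=(), role=role)
        pos += glen + 100
    (c,) = [x for x in classify_clusters(t.finalize(), archs)
            if x.status == "authentic"]
    return c, t, archs


class TestOverlapsProphage:
    def test_full_containment(self):
        c, _, _ = _cluster(10_000)
        assert overlaps_prophage(c, [Interval("c1", 5_000, 40_000)])

    def test_single_bp_overlap_counts(self):
        c, _, _ = _cluster(10_000)
        end = c.candidate.span[1]
        assert overlaps_prophage(c, [Interval("c1", end, end + 5_000)])

    def test_containment_mode_rejects_partial(self):
        c, _, _ = _cluster(10_000)
        end = c.candidate.span[1]
        iv = [Interval("c1", end, end + 5_000)]
        assert overlaps_prophage(c, iv, require_containment=True) == []

    def test_other_contig_ignored(self):
        c, _, _ = _cluster(10_000)
        assert overlaps_prophage(c, [Interval("c9", 1, 1_000_000)]) == []


class TestRescueP4:
    def test_psu_within_window(self):
        c, t, a = _cluster(extra_roles=["other"] * 7 + ["Psu"])
        (ev,) = rescue_p4(c, t, a, window_genes=20)
        assert ev.kind == "psu_gene" and ev.distance_genes == 8

    def test_psu_outside_window(self):
        c, t, a = _cluster(extra_roles=["other"] * 24 + ["Psu"])
        assert rescue_p4(c, t, a, window_genes=20) == []

    def test_prophage_takes_precedence_but_keeps_psu_evidence(self):
        c, t, a = _cluster(extra_roles=["other", "Psu"])
        iv = [Interval("c1", 1, 1_000_000)]
        ann = annotate_contexts([c], t, a, iv, {})[0]
        assert ann.category == "prophage"
        assert {e.kind for e in ann.evidence} == {"prophage_interval",
                                                  "psu_gene"}


class TestMgeLinked:
    def test_two_genes_upstream_is_linked(self):
        c, t, a = _cluster(extra_roles=["other", "other"], n_lead=2)
        ev = mge_linked(c, t, {"g0": "transposase"})
        assert len(ev) == 1 and ev[0].distance_genes == 2

    @pytest.mark.parametrize("gene_arm,bp_arm,expect", [
        (True, True, True), (True, False, True),
        (False, True, True), (False, False, False),
    ])
    def test_or_semantics_truth_table(self, gene_arm, bp_arm, expect):
        # place an MGE gene whose gene-distance and bp-distance arms
        # pass/fail independently, and check linked == OR of the arms
        c, t, a = _cluster()
        span = c.candidate.span
        n_away = 3 if gene_arm else 7  # <=5 genes vs >5 genes
        gap = 500 if bp_arm else 5_000  # <=3000 bp vs >3000 bp
        # build a custom neighbor at controlled index and bp offsets
        t2 = GenomeTable("G2")
        archs = {}
        pos = 1_000
        for i, role in enumerate(["PP2C", "Pkinase_CSD", "Pkinase_FHA"]):
            gid = f"g{i}"
            t2.add(GeneRecord(gid, "c1", pos, pos + 1099, "+"))
            archs[gid] = GeneArchitecture(gene_id=gid, segments=(), role=role)
            pos += 1200
        # intervening small genes to set the index distance
        for j in range(n_away - 1):
            gid = f"f{j}"
            t2.add(GeneRecord(gid, "c1", pos, pos + 59, "+"))
            archs[gid] = GeneArchitecture(gene_id=gid, segments=(),
                                          role="other")
            pos += 70
        mge_start = pos + gap
        t2.add(GeneRecord("mge", "c1", mge_start, mge_start + 999, "+"))
        archs["mge"] = GeneArchitecture(gene_id="mge", segments=(),
                                        role="other")
        (c2,) = classify_clusters(t2.finalize(), archs)
        got = mge_linked(c2, t2, {"mge": "integrase"})
        assert bool(got) == expect

    def test_enlarging_windows_is_monotone(self, small_dataset):
        for gid in small_dataset.genome_ids:
            table, archs, _, mge = load_genome(small_dataset, gid)
            clusters = classify_clusters(table, archs)
            for c in clusters:
                prev = -1
                for wg, wbp in [(2, 1000), (5, 3000), (10, 8000)]:
                    n = len(mge_linked(c, table, mge, wg, wbp))
                    assert n >= prev
                    prev = n


class TestAssignContext:
    def _ann(self, prophage, psu, mge):
        c, _, _ = _cluster()
        pe = [Evidence("prophage_interval", "x")] if prophage else []
        se = [Evidence("psu_gene", "y")] if psu else []
        me = [Evidence("mge_gene", "z")] if mge else []
        return assign_context(c, pe, se, me)

    def test_precedence_table_exhaustive(self):
        for prophage, psu, mge in itertools.product([0, 1], repeat=3):
            cat = self._ann(prophage, psu, mge).category
            if prophage:
                assert cat == "prophage"
            elif psu:
                assert cat == "P4_prophage"
            elif mge:
                assert cat == "MGE_linked"
            else:
                assert cat == "other"

    def test_total_function_fractions_sum_to_one(self, small_dataset):
        total = 0.0
        anns = []
        for gid in small_dataset.genome_ids:
            table, archs, iv, mge = load_genome(small_dataset, gid)
            clusters = classify_clusters(table, archs)
            anns += annotate_contexts(clusters, table, archs, iv, mge)
        df = summarize_contexts(anns)
        overall = df[df.taxon == "all"]
        assert overall.fraction.sum() == pytest.approx(1.0, abs=1e-12)
        assert overall["count"].sum() == len(anns)


class TestSummarize:
    def test_fixture_fractions_and_mge_share(self):
        anns = (
            [ContextAnnotation(f"c{i}", "prophage") for i in range(90)]
            + [ContextAnnotation(f"m{i}", "MGE_linked") for i in range(7)]
            + [ContextAnnotation(f"o{i}", "other") for i in range(3)]
        )
        df = summarize_contexts(anns)
        row = df[(df.taxon == "all") & (df.category == "prophage")].iloc[0]
        assert row.fraction == pytest.approx(0.90)
        mrow = df[(df.taxon == "all") & (df.category == "MGE_linked")].iloc[0]
        assert mrow.mge_among_non_prophage == "7 out of 10"

    def test_single_annotation_is_total(self):
        df = summarize_contexts([ContextAnnotation("c0", "P4_prophage")])
        row = df[(df.taxon == "all") & (df.category == "P4_prophage")].iloc[0]
        assert row.fraction == pytest.approx(1.0)

    def test_per_taxon_rows(self):
        anns = [ContextAnnotation("a", "prophage"),
                ContextAnnotation("b", "other")]
        df = summarize_contexts(anns, taxa={"a": "Proteo", "b": "Bactero"})
        assert set(df.taxon) == {"all", "Proteo", "Bactero"}
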