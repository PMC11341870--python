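from __future__ import annotations

import hashlib
from pathlib import Path

import pytest

from helpers import brute_force_clusters, clusters_to_oracle_set
from kkpscan.context import annotate_contexts
from kkpscan.kkp_scan import classify_clusters
from kkpscan.simulate import (
    DECOY_CLASSES,
    DECOY_EXPECTATIONS,
    ConfigError,
    SynthConfig,
    generate_dataset,
    load_genome,
    load_planted_proteins,
)


def _tree_digest(root: Path) -> dict[str, str]:
    out = {}
    for p in sorted(root.rglob("*")):
        if p.is_file():
            out[str(p.relative_to(root))] = hashlib.sha256(
                p.read_bytes()).hexdigest()
    return out


class TestDeterminism:
    def test_same_seed_byte_identical(self, tmp_path):
        cfg = dict(n_genomes=3, genes_per_genome=80, n_authentic=4,
                   decoy_counts={"LEN_OUT": 1, "NO_CSD": 1})
        a = generate_dataset(SynthConfig(seed=42, **cfg), tmp_path / "a")
        b = generate_dataset(SynthConfig(seed=42, **cfg), tmp_path / "b")
        assert _tree_digest(a.out_dir) == _tree_digest(b.out_dir)

    def test_different_seed_differs(self, tmp_path):
        cfg = dict(n_genomes=2, genes_per_genome=60, n_authentic=2,
                   decoy_counts={})
        a = generate_dataset(SynthConfig(seed=1, **cfg), tmp_path / "a")
        b = generate_dataset(SynthConfig(seed=2, **cfg), tmp_path / "b")
        assert _tree_digest(a.out_dir) != _tree_digest(b.out_dir)

    def test_extending_genomes_preserves_earlier_ones(self, tmp_path):
        cfg = dict(genes_per_genome=60, n_authentic=2, decoy_counts={})
        a = generate_dataset(SynthConfig(seed=9, n_genomes=2, **cfg),
                             tmp_path / "a")
        b = generate_dataset(SynthConfig(seed=9, n_genomes=4, **cfg),
                             tmp_path / "b")
        for gid in a.genome_ids:
            assert (a.gff(gid).read_bytes() == b.gff(gid).read_bytes())
            assert (a.fna(gid).read_bytes() == b.fna(gid).read_bytes())


class TestPlantedTruth:
    def _truth_authentic(self, ds):
        return ds.truth[ds.truth.klass == "authentic"]

    @pytest.mark.parametrize("seed", range(4))
    def test_recall_and_precision_are_one(self, seed, dataset_factory):
        ds = dataset_factory(seed=200 + seed, n_genomes=5,
                             genes_per_genome=100, n_authentic=6)
        planted = {
            (row.genome_id, frozenset(row.gene_ids.split(",")))
            for row in self._truth_authentic(ds).itertuples()
        }
        found = set()
        for gid in ds.genome_ids:
            table, archs, _, _ = load_genome(ds, gid)
            for c in classify_clusters(table, archs):
                if c.status == "authentic":
                    found.add((gid, frozenset(
                        g.gene_id for g in c.candidate.genes)))
        assert found == planted

    def test_context_recovery_is_exact(self, small_dataset):
        ds = small_dataset
        want = {row.item_id: row.context
                for row in self._truth_authentic(ds).itertuples()}
        gene_to_item = {}
        for row in self._truth_authentic(ds).itertuples():
            for g in row.gene_ids.split(","):
                gene_to_item[g] = row.item_id
        got = {}
        for gid in ds.genome_ids:
            table, archs, iv, mge = load_genome(ds, gid)
            clusters = classify_clusters(table, archs)
            anns = annotate_contexts(clusters, table, archs, iv, mge)
            for c, a in zip(clusters, anns):
                if c.status != "authentic":
                    continue
                item = gene_to_item[c.candidate.genes[0].gene_id]
                got[item] = a.category
        assert got == want


class TestDecoys:
    def test_each_class_matches_its_expectation(self, small_dataset):
        ds = small_dataset
        by_genome = {}
        for gid in ds.genome_ids:
            table, archs, _, _ = load_genome(ds, gid)
            by_genome[gid] = classify_clusters(table, archs)
        seen_classes = set()
        for row in ds.truth[ds.truth.klass != "authentic"].itertuples():
            genes = frozenset(row.gene_ids.split(","))
            matching = [
                c for c in by_genome[row.genome_id]
                if frozenset(g.gene_id for g in c.candidate.genes) & genes
            ]
            expect = DECOY_EXPECTATIONS[row.klass]
            if expect is None:
                assert matching == [], row.klass
            else:
                (c,) = matching
                assert c.status == "rejected"
                assert set(c.report.reasons) == {row.expected_reason}
                assert row.expected_reason in expect
            seen_classes.add(row.klass)
        assert seen_classes == set(DECOY_CLASSES)

    def test_decoys_never_score_authentic_with_oracle_agreement(
            self, small_dataset):
        for gid in small_dataset.genome_ids:
            table, archs, _, _ = load_genome(small_dataset, gid)
            got = clusters_to_oracle_set(classify_clusters(table, archs))
            assert got == brute_force_clusters(table, archs)


class TestConfigValidation:
    def test_more_items_than_capacity_rejected(self, tmp_path):
        with pytest.raises(ConfigError):
            generate_dataset(SynthConfig(seed=0, n_genomes=1,
                                         genes_per_genome=40,
                                         n_authentic=50), tmp_path)

    def test_bad_context_mix_rejected(self, tmp_path):
        cfg = SynthConfig(seed=0, context_mix={"prophage": 0.5, "other": 0.2})
        with pytest.raises(ConfigError):
            generate_dataset(cfg, tmp_path)

    def test_unknown_decoy_class_rejected(self, tmp_path):
        cfg = SynthConfig(seed=0, decoy_counts={"BOGUS": 1})
        with pytest.raises(ConfigError):
            generate_dataset(cfg, tmp_path)


class TestEmittedArtifacts:
    def test_planted_cluster_genes_in_length_band(self, small_dataset):
        truth = small_dataset.truth
        for gid in small_dataset.genome_ids:
            table, _, _, _ = load_genome(small_dataset, gid)
            for row in truth[(truth.genome_id == gid)
                             & (truth.klass == "authentic")].itertuples():
                for g in row.gene_ids.split(","):
                    assert 900 < table.get(g).length_bp < 1300

    def test_prophage_items_lie_inside_an_interval(self, small_dataset):
        truth = small_dataset.truth
        for gid in small_dataset.genome_ids:
            table, _, intervals, _ = load_genome(small_dataset, gid)
            rows = truth[(truth.genome_id == gid)
                         & (truth.context == "prophage")]
            for row in rows.itertuples():
                genes = [table.get(g) for g in row.gene_ids.split(",")]
                lo = min(g.start for g in genes)
                hi = max(g.end for g in genes)
                assert any(iv.start <= lo and hi <= iv.end
                           for iv in intervals)

    def test_all_proteins_emitted_for_authentic_items(self, small_dataset):
        prot = load_planted_proteins(small_dataset)
        auth = set(small_dataset.truth[
            small_dataset.truth.klass == "authentic"].item_id)
        assert set(prot) == auth
        for comps in prot.values():
            assert set(comps) == {"pfkA", "pfkB", "pfpC"}
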