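import numpy as np
import pandas as pd
import pytest

from syngc.gc_metrics import PASS, filter_cds, gc3_50
from syngc.simulate import (
    PRONE,
    RESISTANT,
    SimConfig,
    generate_cds,
    generate_genome_pair,
    packaged_fixture_config,
    simulate_bisulfite_calls,
    write_fixture,
)


def quiet_config(**kw):
    base = dict(
        seed=7, n_chromosomes=2, genes_per_chromosome=30,
        n_inversions=0, n_translocations=0, n_dispersed_duplications=0,
        n_tandem_duplications=0, n_losses=0,
    )
    base.update(kw)
    return SimConfig(**base)


class TestGenerateCds:
    def test_always_valid_under_filters(self, rng):
        for cls in (PRONE, RESISTANT):
            for _ in range(20):
                cds = generate_cds(cls, SimConfig(), rng)
                assert filter_cds(cds) == PASS

    def test_no_internal_stop_codons(self, rng):
        cfg = SimConfig(gc3_target_low=0.0)  # worst case: weak third bases
        for _ in range(50):
            cds = generate_cds(PRONE, cfg, rng)
            codons = {cds[i : i + 3] for i in range(0, len(cds), 3)}
            assert not codons & {"TAA", "TAG", "TGA"}

    def test_extreme_targets(self, rng):
        hi = SimConfig(gc3_target_high=1.0)
        lo = SimConfig(gc3_target_low=0.0)
        assert gc3_50(generate_cds(RESISTANT, hi, rng)) == 1.0
        assert gc3_50(generate_cds(PRONE, lo, rng)) == pytest.approx(0.02)

    def test_target_recovery_within_three_se(self, rng):
        # E[gc3_50] = 0.92 * 49/50 + 1/50 = 0.9216 at target 0.92
        cfg = SimConfig()
        n = 2000
        vals = [gc3_50(generate_cds(RESISTANT, cfg, rng)) for _ in range(n)]
        expected = 0.92 * 49 / 50 + 1 / 50
        se = np.sqrt(0.92 * 0.08 / 50 / n)
        assert abs(np.mean(vals) - expected) <= 3 * se


class TestGenomePair:
    def test_identity_case_all_syntenic(self):
        cfg = quiet_config()
        gs_a, gs_b, anchors, truth = generate_genome_pair(cfg)
        assert len(gs_a) == len(gs_b) == 60
        assert truth.genes["true_syntenic"].all()
        # one truth block per chromosome covering every gene
        assert len(truth.true_blocks["A-B"]) == cfg.n_chromosomes
        assert sum(len(b) for b in truth.true_blocks["A-B"]) == 60
        # identical gene orders
        for chrom in gs_a.chrom_order:
            ids_a = [g.gene_id[2:] for g in gs_a.by_chromosome()[chrom]]
            ids_b = [g.gene_id[2:] for g in gs_b.by_chromosome()[chrom]]
            assert ids_a == ids_b

    def test_dispersed_duplication_with_loss_breaks_synteny(self):
        cfg = quiet_config(n_dispersed_duplications=3, loss_after_duplication=1.0)
        _, _, _, truth = generate_genome_pair(cfg)
        df = truth.genes
        dispersed = df[df["origin"] == "dispersed"]
        # each lineage applied 3 events; chained re-duplication of an earlier
        # copy (with loss of its precursor) can merge events, so >= 1 survives
        assert dispersed.groupby("species").size().min() >= 1
        assert not dispersed["true_syntenic"].any()

    def test_fixed_seed_reproducible(self):
        cfg = packaged_fixture_config()
        a1 = generate_genome_pair(cfg)
        a2 = generate_genome_pair(cfg)
        assert [g.cds for g in a1[0].genes.values()] == [g.cds for g in a2[0].genes.values()]
        assert a1[2] == a2[2]
        pd.testing.assert_frame_equal(a1[3].genes, a2[3].genes)
        assert a1[3].genome_seqs == a2[3].genome_seqs

    def test_seed_changes_output(self):
        import dataclasses

        cfg = packaged_fixture_config()
        other = dataclasses.replace(cfg, seed=43)
        assert (
            generate_genome_pair(cfg)[3].genome_seqs
            != generate_genome_pair(other)[3].genome_seqs
        )

    def test_truth_blocks_obey_block_contract(self, small_pair):
        gs_a, gs_b, _, truth = small_pair
        for blk in truth.true_blocks["A-B"]:
            oa = [gs_a[a].ordinal for a, _ in blk]
            ob = [gs_b[b].ordinal for _, b in blk]
            assert len(blk) >= 7
            assert oa == sorted(oa)
            assert ob == sorted(ob) or ob == sorted(ob, reverse=True)

    def test_oversized_event_counts_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(n_chromosomes=1, genes_per_chromosome=10, n_losses=100)

    def test_class_coupling_direction(self, small_pair):
        # non-syntenic genes are enriched for the duplication-prone class
        _, _, _, truth = small_pair
        df = truth.genes
        prone_rate = lambda sel: (sel["class_label"] == PRONE).mean()
        assert prone_rate(df[~df["true_syntenic"]]) > prone_rate(df[df["true_syntenic"]])


class TestBisulfite:
    def test_degenerate_beta_fully_methylated(self):
        cfg = quiet_config(n_chromosomes=1, genes_per_chromosome=5)
        cfg.meth_beta_params = {
            PRONE: {c: (1e6, 1e-3) for c in ("CG", "CHG", "CHH")},
            RESISTANT: {c: (1e6, 1e-3) for c in ("CG", "CHG", "CHH")},
        }
        gs_a, _, _, truth = generate_genome_pair(cfg)
        calls = simulate_bisulfite_calls(gs_a, truth, cfg)
        assert (calls.df["m_reads"] == calls.df["total_reads"]).all()

    def test_zero_depth_gives_uncovered_rows(self):
        cfg = quiet_config(n_chromosomes=1, genes_per_chromosome=5, read_depth=0)
        gs_a, _, _, truth = generate_genome_pair(cfg)
        calls = simulate_bisulfite_calls(gs_a, truth, cfg)
        assert (calls.df["total_reads"] == 0).all() and calls.n_uncovered == len(calls)

    def test_contexts_match_genome_sequence(self, small_pair):
        from syngc.methylation import assign_context

        gs_a, _, _, truth = small_pair
        cfg = packaged_fixture_config()
        calls = simulate_bisulfite_calls(gs_a, truth, cfg)
        sample = calls.df.sample(n=200, random_state=0)
        for row in sample.itertuples(index=False):
            assert assign_context(
                truth.genome_seqs["A"], row.chrom, row.pos, row.strand
            ) == row.context


class TestFixtureFiles:
    def test_fixture_reproducible_and_complete(self, tmp_path):
        import hashlib

        cfg = quiet_config(n_dispersed_duplications=2)
        d1, d2 = tmp_path / "f1", tmp_path / "f2"
        write_fixture(d1, cfg)
        write_fixture(d2, cfg)
        names = sorted(p.name for p in d1.iterdir())
        assert {"genome_A.fa", "cds_A.fa", "genes_A.gff3", "allc_A.tsv",
                "anchors_A_B.tsv", "truth_genes.tsv", "truth_blocks.tsv"} <= set(names)
        for name in names:
            h1 = hashlib.sha256((d1 / name).read_bytes()).hexdigest()
            h2 = hashlib.sha256((d2 / name).read_bytes()).hexdigest()
            assert h1 == h2, name

    def test_truth_gene_count_matches_gff3(self, tmp_path):
        cfg = quiet_config(n_dispersed_duplications=4, n_losses=3)
        write_fixture(tmp_path / "f", cfg)
        truth = pd.read_csv(tmp_path / "f" / "truth_genes.tsv", sep="\t")
        n_gff = sum(
            1 for line in open(tmp_path / "f" / "genes_A.gff3")
            if "\tgene\t" in line
        )
        assert (truth["species"] == "A").sum() == n_gff
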