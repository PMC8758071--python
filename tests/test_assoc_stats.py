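import numpy as np
import pytest
from scipy import stats as sps

from syngc.assoc_stats import (
    correlate,
    gc3_50_distribution,
    go_enrichment,
    methylation_by_gc3_bins,
    wilcoxon_rank_sum,
)
from syngc.methylation import GeneMethylation
from syngc.synteny import SyntenyStatus
from tests.oracles import hypergeom_upper_tail, permutation_rank_sum_p


class TestWilcoxon:
    def test_identical_samples_p_one(self):
        x = [1.0, 2.0, 3.0, 4.0]
        _, p = wilcoxon_rank_sum(x, x, mode="exact")
        assert p == pytest.approx(1.0)

    def test_separated_triples_exact_p(self):
        # full enumeration over C(6,3)=20 arrangements: 2 extreme ones
        _, p = wilcoxon_rank_sum([1, 2, 3], [4, 5, 6], mode="exact")
        assert p == pytest.approx(0.1)

    def test_exact_matches_permutation_oracle_with_ties(self, rng):
        for _ in range(25):
            nx = int(rng.integers(2, 7))
            ny = int(rng.integers(2, 7))
            pool = rng.integers(0, 4, size=nx + ny).astype(float)  # heavy ties
            x, y = list(pool[:nx]), list(pool[nx:])
            w, p = wilcoxon_rank_sum(x, y, mode="exact")
            w_ref, p_ref = permutation_rank_sum_p(x, y)
            assert w == pytest.approx(w_ref)
            assert p == pytest.approx(p_ref, abs=1e-12)

    def test_auto_mode_approx_agrees_with_scipy(self, rng):
        x = rng.normal(0, 1, size=50)
        y = rng.normal(0.5, 1, size=60)
        _, p = wilcoxon_rank_sum(x, y, mode="auto")
        ref = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        assert p == pytest.approx(ref.pvalue)

    def test_empty_sample_is_error(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1.0])


class TestCorrelate:
    def test_perfect_linear(self):
        x = [1.0, 2.0, 3.0, 4.0]
        y = [2 * v + 1 for v in x]
        r, p = correlate(x, y, "pearson")
        assert r == pytest.approx(1.0)

    def test_constant_vector_undefined(self):
        r, p = correlate([1, 2, 3], [5, 5, 5], "pearson")
        assert r is None and p is None

    def test_ten_pair_closed_form(self, rng):
        x = rng.normal(size=10)
        y = rng.normal(size=10)
        r, _ = correlate(x, y, "pearson")
        sx, sy = x - x.mean(), y - y.mean()
        expected = (sx * sy).sum() / np.sqrt((sx**2).sum() * (sy**2).sum())
        assert r == pytest.approx(expected)

    def test_na_pairs_dropped(self):
        x = [1.0, 2.0, np.nan, 4.0, 5.0]
        y = [1.1, 1.9, 3.0, np.nan, 5.2]
        r, _ = correlate(x, y, "pearson")
        r_ref, _ = correlate([1.0, 2.0, 5.0], [1.1, 1.9, 5.2], "pearson")
        assert r == pytest.approx(r_ref)

    def test_spearman_monotone_transform_invariant(self, rng):
        x = rng.normal(size=30)
        y = np.exp(x) + rng.normal(scale=1e-9, size=30)
        r, _ = correlate(x, y, "spearman")
        assert r == pytest.approx(1.0)


class TestHistogram:
    def test_single_gene_lands_in_its_bin(self):
        table = gc3_50_distribution({"g": 0.94}, {"g": "syntenic"})
        assert table.loc[94, "syntenic"] == 1

    def test_totals_conserved(self, rng):
        values = {f"g{i}": int(rng.integers(0, 51)) / 50 for i in range(200)}
        labels = {g: ("a" if rng.random() < 0.5 else "b") for g in values}
        table = gc3_50_distribution(values, labels)
        for grp in ("a", "b"):
            assert table[grp].sum() == sum(1 for g in values if labels[g] == grp)


class TestBinnedCurves:
    def make_gm(self, gid, level, sites):
        gm = GeneMethylation(gid)
        gm.levels = {"CG": level, "CHG": level, "CHH": None}
        gm.n_sites = {"CG": sites, "CHG": sites, "CHH": 0}
        gm.n_reads = {"CG": sites * 10, "CHG": sites * 10, "CHH": 0}
        return gm

    def test_sparse_bin_not_shown(self):
        gms = {"g1": self.make_gm("g1", 0.5, 150)}
        curves = methylation_by_gc3_bins(gms, {"g1": 0.5}, "CHG")
        assert curves[0].n_context_sites == 150 and not curves[0].shown

    def test_dense_bin_shown(self):
        gms = {f"g{i}": self.make_gm(f"g{i}", 0.5, 100) for i in range(3)}
        curves = methylation_by_gc3_bins(gms, {g: 0.5 for g in gms}, "CHG")
        assert curves[0].shown and curves[0].n_context_sites == 300

    def test_single_gene_bin_mean_is_gene_level(self):
        gms = {"g1": self.make_gm("g1", 0.37, 300)}
        curves = methylation_by_gc3_bins(gms, {"g1": 0.2}, "CG")
        assert curves[0].mean_level == pytest.approx(0.37)

    def test_three_bin_hand_tally(self):
        gms = {
            "g1": self.make_gm("g1", 0.1, 100), "g2": self.make_gm("g2", 0.3, 100),
            "g3": self.make_gm("g3", 0.8, 100),
        }
        gc = {"g1": 0.10, "g2": 0.10, "g3": 0.90}
        curves = {c.bin_pct: c for c in methylation_by_gc3_bins(gms, gc, "CG")}
        assert curves[10].mean_level == pytest.approx(0.2)
        assert curves[10].n_genes == 2
        assert curves[90].mean_level == pytest.approx(0.8)


def make_statuses(n_syn, n_non):
    out = {}
    for i in range(n_syn):
        out[f"s{i}"] = SyntenyStatus(f"s{i}", True, ["c"])
    for i in range(n_non):
        out[f"n{i}"] = SyntenyStatus(f"n{i}", False, [])
    return out


class TestGoEnrichment:
    def test_small_term_excluded(self):
        statuses = make_statuses(50, 50)
        go = {g: ["GO:1"] for g in list(statuses)[:19]}
        go.update({g: ["GO:2"] for g in statuses})
        rows = go_enrichment(go, statuses, "sp")
        assert {r.go_term for r in rows} == {"GO:2"}

    def test_balanced_table_not_significant(self):
        statuses = make_statuses(50, 50)
        go = {}
        for i in range(25):
            go[f"s{i}"] = ["GO:1"]
            go[f"n{i}"] = ["GO:1"]
        for g in statuses:
            go.setdefault(g, []).append("GO:2")
        rows = {r.go_term: r for r in go_enrichment(go, statuses, "sp")}
        assert not rows["GO:1"].significant

    def test_tail_sum_matches_direct_enumeration(self):
        # a=15 of 20 term genes syntenic, universe 100/200 split
        statuses = make_statuses(100, 100)
        go = {}
        for i in range(15):
            go[f"s{i}"] = ["GO:1"]
        for i in range(5):
            go[f"n{i}"] = ["GO:1"]
        for g in statuses:
            go.setdefault(g, []).append("GO:0")
        rows = {r.go_term: r for r in go_enrichment(go, statuses, "sp")}
        r = rows["GO:1"]
        assert r.a == 15 and r.b == 5
        expected = hypergeom_upper_tail(15, 20, 100, 200)
        assert r.p_value == pytest.approx(expected)
        assert r.direction == "syntenic"

    def test_hypergeom_pmf_sums_to_one(self):
        total, col1, row1 = 60, 25, 12
        s = sum(
            hypergeom_upper_tail(a, row1, col1, total)
            - hypergeom_upper_tail(a + 1, row1, col1, total)
            for a in range(0, min(row1, col1) + 1)
        )
        assert s == pytest.approx(1.0)

    def test_empty_map_is_error(self):
        with pytest.raises(ValueError):
            go_enrichment({}, make_statuses(5, 5), "sp")
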