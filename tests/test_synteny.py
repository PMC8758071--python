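import numpy as np
import pytest

from syngc.formats_io import AnchorPair
from syngc.synteny import (
    ChainParams,
    chain_anchors,
    classify_synteny,
    collapse_tandem_arrays,
    detect_synteny,
    synteny_summary_matrix,
    validate_block,
)
from tests.conftest import make_geneset
from tests.oracles import brute_force_chain_packing


def diagonal_genesets(n: int):
    gs_a = make_geneset("A", {"c1": [f"a{i}" for i in range(n)]})
    gs_b = make_geneset("B", {"c1": [f"b{i}" for i in range(n)]})
    return gs_a, gs_b


class TestChainAnchors:
    def test_perfect_diagonal_single_block(self):
        gs_a, gs_b = diagonal_genesets(10)
        anchors = [AnchorPair(f"a{i}", f"b{i}") for i in range(10)]
        blocks = chain_anchors(anchors, gs_a, gs_b)
        assert len(blocks) == 1
        assert blocks[0].score == 10 and blocks[0].orientation == "+"

    def test_six_anchors_below_floor(self):
        gs_a, gs_b = diagonal_genesets(6)
        anchors = [AnchorPair(f"a{i}", f"b{i}") for i in range(6)]
        assert chain_anchors(anchors, gs_a, gs_b) == []

    def test_descending_block_minus_orientation(self):
        gs_a, gs_b = diagonal_genesets(7)
        anchors = [AnchorPair(f"a{i}", f"b{6 - i}") for i in range(7)]
        blocks = chain_anchors(anchors, gs_a, gs_b)
        assert len(blocks) == 1 and blocks[0].orientation == "-"

    def test_internal_gap_within_tolerance(self):
        gs_a, gs_b = diagonal_genesets(40)
        idx = [0, 1, 2, 3, 9, 10, 11, 12]  # one gap of 6 ordinals
        anchors = [AnchorPair(f"a{i}", f"b{i}") for i in idx]
        blocks = chain_anchors(anchors, gs_a, gs_b)
        assert len(blocks) == 1 and blocks[0].score == 8

    def test_gap_beyond_tolerance_splits_and_drops(self):
        gs_a, gs_b = diagonal_genesets(40)
        idx = [0, 1, 2, 3, 29, 30, 31, 32]  # gap of 26 > max_gap
        anchors = [AnchorPair(f"a{i}", f"b{i}") for i in idx]
        assert chain_anchors(anchors, gs_a, gs_b) == []

    def test_blocks_satisfy_contract(self, rng):
        gs_a, gs_b = diagonal_genesets(60)
        params = ChainParams(min_anchors=3, max_gap=5, exact_max_anchors=0)
        for _ in range(20):
            anchors = [
                AnchorPair(f"a{i}", f"b{int(rng.integers(0, 60))}")
                for i in sorted(rng.choice(60, size=25, replace=False))
            ]
            blocks = chain_anchors(anchors, gs_a, gs_b, params)
            seen = set()
            for b in blocks:
                validate_block(b, gs_a, gs_b, params)
                for a in b.anchors:
                    key = (a.gene_a, a.gene_b)
                    assert key not in seen  # anchor-disjointness
                    seen.add(key)

    def test_raising_min_anchors_never_adds_syntenic_genes(self, rng):
        gs_a, gs_b = diagonal_genesets(60)
        for trial in range(10):
            anchors = [
                AnchorPair(f"a{i}", f"b{int(rng.integers(0, 60))}")
                for i in sorted(rng.choice(60, size=30, replace=False))
            ]
            counts = []
            for floor in (3, 5, 7, 9):
                params = ChainParams(min_anchors=floor, max_gap=10)
                res = detect_synteny(anchors, gs_a, gs_b, params)
                counts.append(len(res.syntenic_a))
            assert counts == sorted(counts, reverse=True)

    def test_exact_packing_beats_single_greedy_chain(self):
        # a long chain that overlaps two shorter ones; optimum uses the two
        gs_a, gs_b = diagonal_genesets(30)
        pts = [(0, 10), (1, 11), (2, 12), (3, 13), (4, 14), (5, 15),
               (3, 3), (4, 4), (5, 5),
               (6, 16), (7, 17), (8, 18)]
        # chains: the 9 "diagonal+offset" points contain a 6+ chain through
        # (0,10)..(8,18); oracle confirms optimum
        anchors = [AnchorPair(f"a{i}", f"b{j}") for i, j in pts]
        params = ChainParams(min_anchors=3, max_gap=5)
        blocks = chain_anchors(anchors, gs_a, gs_b, params)
        total = sum(b.score for b in blocks)
        assert total == brute_force_chain_packing(pts, 5, 3)


class TestTandemCollapse:
    def test_no_adjacent_homologs_identity(self):
        gs_a, gs_b = diagonal_genesets(10)
        anchors = [AnchorPair(f"a{i}", f"b{i}") for i in range(10)]
        reduced, rep_a, rep_b = collapse_tandem_arrays(
            anchors, gs_a, gs_b, ChainParams()
        )
        assert len(reduced) == len(anchors)

    def test_collapse_disabled_is_identity(self):
        gs_a, gs_b = diagonal_genesets(10)
        anchors = [AnchorPair("a0", "b0"), AnchorPair("a1", "b0")]
        reduced, _, _ = collapse_tandem_arrays(
            anchors, gs_a, gs_b, ChainParams(collapse_tandems=False)
        )
        assert reduced == anchors

    def test_tandem_array_members_inherit_block_status(self):
        # genes a7,a8,a9 all hit b7: collapsed to a7, which chains; all three
        # must come back syntenic
        n = 12
        gs_a = make_geneset("A", {"c1": [f"a{i}" for i in range(n)]})
        gs_b = make_geneset("B", {"c1": [f"b{i}" for i in range(n)]})
        anchors = [AnchorPair(f"a{i}", f"b{i}") for i in range(8)]
        anchors += [AnchorPair("a8", "b7"), AnchorPair("a9", "b7")]
        res = detect_synteny(anchors, gs_a, gs_b, ChainParams(min_anchors=7))
        assert {"a7", "a8", "a9"} <= res.syntenic_a


class TestClassify:
    def test_membership_and_support_tags(self):
        gs_a, gs_b = diagonal_genesets(10)
        anchors = [AnchorPair(f"a{i}", f"b{i}") for i in range(7)]
        res = detect_synteny(anchors, gs_a, gs_b, tag="A-B")
        statuses = classify_synteny(gs_a, [res])
        assert statuses["a0"].syntenic
        assert statuses["a0"].supporting_comparisons == ["A-B"]
        assert not statuses["a9"].syntenic
        assert statuses["a9"].supporting_comparisons == []

    def test_empty_geneset_is_error(self):
        from syngc.formats_io import GeneSet

        with pytest.raises(ValueError):
            classify_synteny(GeneSet("empty"), [])

    def test_summary_matrix_union(self):
        from syngc.synteny import SyntenyStatus

        # disjoint supports of size 3 and 4 -> union 7; nested 5 within 9 -> 9
        disjoint = {}
        for i in range(3):
            disjoint[f"g{i}"] = SyntenyStatus(f"g{i}", True, ["c1"])
        for i in range(3, 7):
            disjoint[f"g{i}"] = SyntenyStatus(f"g{i}", True, ["c2"])
        nested = {}
        for i in range(9):
            tags = ["c1", "c2"] if i < 5 else ["c2"]
            nested[f"h{i}"] = SyntenyStatus(f"h{i}", True, tags)
        m = synteny_summary_matrix({"sp1": disjoint, "sp2": nested})
        assert m.loc["sp1", "union"] == 7
        assert m.loc["sp2", "union"] == 9
        assert m.loc["sp2", "c1"] == 5 and m.loc["sp2", "c2"] == 9

    def test_self_comparison_excludes_identity_diagonal(self):
        gs = make_geneset("A", {"c1": [f"a{i}" for i in range(10)]})
        anchors = [AnchorPair(f"a{i}", f"a{i}") for i in range(10)]
        res = detect_synteny(anchors, gs, gs, tag="A-A")
        assert res.blocks == [] and res.syntenic_a == set()
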