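"""Collinear synteny-block detection between two gene orders.

A block is a run of homologous gene pairs (anchors) whose ordinals are
jointly monotonic in both genomes — ascending in genome A and either
ascending (orientation ``+``) or descending (orientation ``-``) in genome
B — with bounded rank gaps between consecutive anchors and a minimum
number of anchors per block (7 by default, the usual floor for calling a
conserved segment rather than chance collinearity).

Genes inside at least one block of at least one comparison are classified
as syntenic, i.e. still at their ancestral location; all others as
non-syntenic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import IO, Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from syngc.formats_io import AnchorPair, GeneSet


@dataclass
class ChainParams:
    """Tunable knobs of the collinearity chainer.

    min_anchors
        Minimum anchors per reported block.
    max_gap
        Largest allowed gene-rank gap between consecutive anchors of a
        chain, enforced in both genomes.
    collapse_tandems
        Whether tandem arrays of near-adjacent co-homologous genes are
        reduced to one representative before chaining.
    tandem_window
        Maximum ordinal distance for two genes to belong to one tandem
        array.
    exact_max_anchors
        Chromosome-pair anchor count up to which the chainer solves the
        disjoint-chain packing exactly instead of greedily.
    """

    min_anchors: int = 7
    max_gap: int = 20
    collapse_tandems: bool = True
    tandem_window: int = 10
    exact_max_anchors: int = 12

    def __post_init__(self) -> None:
        if self.min_anchors < 2:
            raise ValueError("min_anchors must be >= 2")
        if self.max_gap < 1:
            raise ValueError("max_gap must be >= 1")


@dataclass
class SyntenyBlock:
    """A chained run of anchors collinear between two genomes."""

    anchors: list[AnchorPair]
    orientation: str  # '+' ascending in genome B, '-' descending
    chrom_a: str
    chrom_b: str

    @property
    def score(self) -> int:
        return len(self.anchors)


@dataclass
class SyntenyStatus:
    gene_id: str
    syntenic: bool
    supporting_comparisons: list[str] = field(default_factory=list)


@dataclass
class SyntenyResult:
    """Blocks of one pairwise comparison plus the derived syntenic gene sets.

    The syntenic sets already include tandem-array members folded into a
    block through their representative.
    """

    tag: str
    species_a: str
    species_b: str
    blocks: list[SyntenyBlock]
    syntenic_a: set[str]
    syntenic_b: set[str]


class _UnionFind:
    def __init__(self):
        self.parent: dict[str, str] = {}

    def find(self, x: str) -> str:
        p = self.parent.setdefault(x, x)
        if p != x:
            p = self.parent[x] = self.find(p)
        return p

    def union(self, x: str, y: str) -> None:
        rx, ry = self.find(x), self.find(y)
        if rx != ry:
            self.parent[ry] = rx


def _tandem_arrays(
    anchors: Sequence[AnchorPair], geneset: GeneSet, side: str, window: int
) -> dict[str, str]:
    """Member -> representative map for tandem arrays on one genome side.

    Two genes form an array when they lie on the same chromosome within
    ``window`` ordinals of each other and share at least one anchor
    partner; arrays are the transitive closure of that relation, and the
    lowest-ordinal member represents the array.
    """
    by_partner: dict[str, list[str]] = {}
    for a in anchors:
        g, p = (a.gene_a, a.gene_b) if side == "a" else (a.gene_b, a.gene_a)
        by_partner.setdefault(p, []).append(g)

    uf = _UnionFind()
    for members in by_partner.values():
        ms = sorted(set(members), key=lambda g: (geneset[g].chrom, geneset[g].ordinal))
        for g1, g2 in zip(ms, ms[1:]):
            m1, m2 = geneset[g1], geneset[g2]
            if m1.chrom == m2.chrom and m2.ordinal - m1.ordinal <= window:
                uf.union(g1, g2)

    clusters: dict[str, list[str]] = {}
    for g in uf.parent:
        clusters.setdefault(uf.find(g), []).append(g)
    rep_map: dict[str, str] = {}
    for members in clusters.values():
        rep = min(members, key=lambda g: (geneset[g].chrom, geneset[g].ordinal))
        for g in members:
            rep_map[g] = rep
    return rep_map


def collapse_tandem_arrays(
    anchors: Sequence[AnchorPair],
    geneset_a: GeneSet,
    geneset_b: GeneSet,
    params: ChainParams,
) -> tuple[list[AnchorPair], dict[str, str], dict[str, str]]:
    """Reduce tandem arrays to single representative anchors.

    Returns the reduced anchor list plus member->representative maps for
    both genomes, so synteny status assigned to a representative can be
    propagated back to every collapsed member.
    """
    if not params.collapse_tandems:
        return list(anchors), {}, {}
    rep_a = _tandem_arrays(anchors, geneset_a, "a", params.tandem_window)
    rep_b = _tandem_arrays(anchors, geneset_b, "b", params.tandem_window)
    seen: set[tuple[str, str]] = set()
    reduced: list[AnchorPair] = []
    for a in anchors:
        ga = rep_a.get(a.gene_a, a.gene_a)
        gb = rep_b.get(a.gene_b, a.gene_b)
        if (ga, gb) not in seen:
            seen.add((ga, gb))
            reduced.append(AnchorPair(ga, gb, a.score))
    return reduced, rep_a, rep_b


def _dp_best_chain(oa: np.ndarray, ob: np.ndarray, max_gap: int) -> list[int]:
    """Longest chain under 0 < delta <= max_gap in both coordinates.

    Anchors must be pre-sorted by (oa, ob).  Returns indices of the best
    chain; ties break toward the smallest start index, making extraction
    deterministic.
    """
    n = len(oa)
    if n == 0:
        return []
    dp = np.ones(n, dtype=np.int64)
    prev = np.full(n, -1, dtype=np.int64)
    for i in range(1, n):
        ok = (
            (oa[:i] < oa[i])
            & (oa[:i] >= oa[i] - max_gap)
            & (ob[:i] < ob[i])
            & (ob[:i] >= ob[i] - max_gap)
        )
        if ok.any():
            cand = np.where(ok)[0]
            best = cand[np.argmax(dp[cand])]
            dp[i] = dp[best] + 1
            prev[i] = best
    end = int(np.argmax(dp))  # argmax returns the first maximum: lowest end index
    chain = []
    while end != -1:
        chain.append(end)
        end = int(prev[end])
    chain.reverse()
    return chain


def chain_anchors(
    anchors: Sequence[AnchorPair],
    geneset_a: GeneSet,
    geneset_b: GeneSet,
    params: Optional[ChainParams] = None,
) -> list[SyntenyBlock]:
    """Chain anchors into collinear blocks with a longest-chain DP.

    Per chromosome pair and orientation, anchors are linked when their
    ordinal deltas satisfy ``0 < da <= max_gap`` and ``0 < |db| <= max_gap``
    with the orientation's sign.  Chains are extracted best-score-first
    (ties: smaller start ordinal, then ``+`` before ``-``), each anchor
    entering at most one block; chromosome pairs with at most
    ``exact_max_anchors`` anchors are instead packed optimally.  Chains
    shorter than ``min_anchors`` are discarded.  Blocks come back sorted
    by (chrom_a, first a-ordinal).
    """
    params = params or ChainParams()
    by_pair: dict[tuple[str, str], list[AnchorPair]] = {}
    for a in anchors:
        key = (geneset_a[a.gene_a].chrom, geneset_b[a.gene_b].chrom)
        by_pair.setdefault(key, []).append(a)

    blocks: list[SyntenyBlock] = []
    for (ca, cb), group in sorted(by_pair.items()):
        idx_points = [
            (geneset_a[a.gene_a].ordinal, geneset_b[a.gene_b].ordinal, i)
            for i, a in enumerate(group)
        ]
        if len(group) <= params.exact_max_anchors:
            chains = _exact_pack_both_orientations(
                idx_points, params.max_gap, params.min_anchors
            )
        else:
            chains = _greedy_both_orientations(
                idx_points, params.max_gap, params.min_anchors
            )
        for chain_indices in chains:
            members = sorted(
                (group[i] for i in chain_indices),
                key=lambda a: geneset_a[a.gene_a].ordinal,
            )
            b_ords = [geneset_b[a.gene_b].ordinal for a in members]
            orientation = "+" if b_ords[-1] > b_ords[0] else "-"
            blocks.append(SyntenyBlock(members, orientation, ca, cb))

    blocks.sort(
        key=lambda b: (b.chrom_a, geneset_a[b.anchors[0].gene_a].ordinal, b.orientation)
    )
    return blocks


def _greedy_both_orientations(
    idx_points: list[tuple[int, int, int]], max_gap: int, min_anchors: int
) -> list[list[int]]:
    """Alternate best-first extraction across the two orientations."""
    remaining = dict((p[2], p) for p in idx_points)
    chains: list[list[int]] = []
    while True:
        pts = list(remaining.values())
        if len(pts) < min_anchors:
            break
        best_chain: list[int] = []
        best_key = None
        for sign, orient_rank in (((1), 0), ((-1), 1)):
            points = [(oa, sign * ob, i) for oa, ob, i in pts]
            sub = sorted(points)
            oa = np.array([p[0] for p in sub])
            ob = np.array([p[1] for p in sub])
            chain = _dp_best_chain(oa, ob, max_gap)
            if len(chain) < min_anchors:
                continue
            start_ord = sub[chain[0]][0]
            key = (-len(chain), start_ord, orient_rank)
            if best_key is None or key < best_key:
                best_key = key
                best_chain = [sub[i][2] for i in chain]
        if not best_chain:
            break
        chains.append(best_chain)
        for i in best_chain:
            del remaining[i]
    return chains


def _exact_pack_both_orientations(
    idx_points: list[tuple[int, int, int]], max_gap: int, min_anchors: int
) -> list[list[int]]:
    """Exact packing allowing chains of either orientation.

    Chains of the two orientations compete for the same anchors, so the
    search branches over orientation per chain: enumerate packings where
    each chain is monotone ascending in either +b or -b.
    """
    n = len(idx_points)
    pts = sorted(idx_points)
    oa = [p[0] for p in pts]
    ob = [p[1] for p in pts]

    from functools import lru_cache

    def can_follow(j: int, i: int, sign: int) -> bool:
        da = oa[i] - oa[j]
        db = sign * (ob[i] - ob[j])
        return 0 < da <= max_gap and 0 < db <= max_gap

    @lru_cache(maxsize=None)
    def chains_through_first(mask: int, sign: int) -> tuple[tuple[int, ...], ...]:
        first = (mask & -mask).bit_length() - 1
        out: list[tuple[int, ...]] = []

        def extend(chain: tuple[int, ...]) -> None:
            out.append(chain)
            last = chain[-1]
            for i in range(last + 1, n):
                if (mask >> i) & 1 and can_follow(last, i, sign):
                    extend(chain + (i,))

        extend((first,))
        return tuple(out)

    @lru_cache(maxsize=None)
    def best(mask: int) -> tuple[int, tuple]:
        if mask == 0:
            return 0, ()
        first = (mask & -mask).bit_length() - 1
        score, packing = best(mask & ~(1 << first))
        for sign in (1, -1):
            for chain in chains_through_first(mask, sign):
                if len(chain) < min_anchors:
                    continue
                sub = mask
                for i in chain:
                    sub &= ~(1 << i)
                s, p = best(sub)
                if s + len(chain) > score:
                    score, packing = s + len(chain), (chain,) + p
        return score, packing

    _, packing = best((1 << n) - 1)
    return [[pts[i][2] for i in chain] for chain in packing]


def detect_synteny(
    anchors: Sequence[AnchorPair],
    geneset_a: GeneSet,
    geneset_b: GeneSet,
    params: Optional[ChainParams] = None,
    tag: Optional[str] = None,
) -> SyntenyResult:
    """Full comparison: tandem collapse, chaining, membership propagation.

    For a self-comparison (same species tag on both sides) the identity
    diagonal — each gene matched to itself — is removed before chaining,
    so self-synteny reflects retained duplicates from ancient polyploidy
    rather than the trivial match of a genome to itself.
    """
    params = params or ChainParams()
    tag = tag or f"{geneset_a.species_tag}-{geneset_b.species_tag}"
    if geneset_a.species_tag == geneset_b.species_tag:
        anchors = [a for a in anchors if a.gene_a != a.gene_b]
    reduced, rep_a, rep_b = collapse_tandem_arrays(anchors, geneset_a, geneset_b, params)
    blocks = chain_anchors(reduced, geneset_a, geneset_b, params) if reduced else []

    members_a: dict[str, set[str]] = {}
    members_b: dict[str, set[str]] = {}
    for g, rep in rep_a.items():
        members_a.setdefault(rep, set()).add(g)
    for g, rep in rep_b.items():
        members_b.setdefault(rep, set()).add(g)

    syn_a: set[str] = set()
    syn_b: set[str] = set()
    for block in blocks:
        for a in block.anchors:
            syn_a |= members_a.get(a.gene_a, {a.gene_a})
            syn_b |= members_b.get(a.gene_b, {a.gene_b})
    return SyntenyResult(tag, geneset_a.species_tag, geneset_b.species_tag,
                         blocks, syn_a, syn_b)


def classify_synteny(
    geneset: GeneSet, results: Iterable[SyntenyResult]
) -> dict[str, SyntenyStatus]:
    """Per-gene synteny status of one species across comparisons.

    A gene is syntenic iff it belongs to at least one block (directly or
    as a collapsed tandem member) in at least one comparison involving the
    species.
    """
    if len(geneset) == 0:
        raise ValueError("empty gene set")
    supporting: dict[str, list[str]] = {g: [] for g in geneset.genes}
    for res in results:
        if res.species_a == geneset.species_tag:
            for g in res.syntenic_a:
                if g in supporting:
                    supporting[g].append(res.tag)
        if res.species_b == geneset.species_tag and res.species_a != res.species_b:
            for g in res.syntenic_b:
                if g in supporting:
                    supporting[g].append(res.tag)
        elif res.species_b == geneset.species_tag and res.species_a == res.species_b:
            for g in res.syntenic_b:
                if g in supporting and res.tag not in supporting[g]:
                    supporting[g].append(res.tag)
    return {
        g: SyntenyStatus(g, bool(tags), sorted(set(tags)))
        for g, tags in supporting.items()
    }


def synteny_summary_matrix(
    statuses_by_species: Mapping[str, Mapping[str, SyntenyStatus]]
) -> pd.DataFrame:
    """Count of syntenic genes per species and comparison, plus the union.

    Mirrors the species x comparison grid used to summarise how many
    genes of each genome sit in a conserved location elsewhere.
    """
    rows = {}
    for species, statuses in statuses_by_species.items():
        counts: dict[str, int] = {}
        union = 0
        for st in statuses.values():
            if st.syntenic:
                union += 1
            for tag in st.supporting_comparisons:
                counts[tag] = counts.get(tag, 0) + 1
        counts["union"] = union
        rows[species] = counts
    df = pd.DataFrame.from_dict(rows, orient="index").fillna(0).astype(int)
    cols = [c for c in sorted(df.columns) if c != "union"] + ["union"]
    return df[cols]


def validate_block(
    block: SyntenyBlock, geneset_a: GeneSet, geneset_b: GeneSet, params: ChainParams
) -> None:
    """Assert the double-monotonicity, gap and size contract of a block."""
    oa = [geneset_a[a.gene_a].ordinal for a in block.anchors]
    ob = [geneset_b[a.gene_b].ordinal for a in block.anchors]
    sign = 1 if block.orientation == "+" else -1
    if len(block.anchors) < params.min_anchors:
        raise AssertionError("block below min_anchors")
    for (a1, b1), (a2, b2) in zip(zip(oa, ob), zip(oa[1:], ob[1:])):
        if not (0 < a2 - a1 <= params.max_gap):
            raise AssertionError("a-ordinal gap violation")
        if not (0 < sign * (b2 - b1) <= params.max_gap):
            raise AssertionError("b-ordinal gap violation")


def write_blocks_tsv(
    blocks: Sequence[SyntenyBlock],
    geneset_a: GeneSet,
    geneset_b: GeneSet,
    tag: str,
    dest: IO,
) -> None:
    dest.write(
        "comparison\tblock_id\tchrom_a\tchrom_b\torientation\tn_anchors\t"
        "a_start\ta_end\tb_start\tb_end\n"
    )
    for i, b in enumerate(blocks):
        oa = [geneset_a[x.gene_a].ordinal for x in b.anchors]
        ob = [geneset_b[x.gene_b].ordinal for x in b.anchors]
        dest.write(
            f"{tag}\t{i}\t{b.chrom_a}\t{b.chrom_b}\t{b.orientation}\t{b.score}\t"
            f"{min(oa)}\t{max(oa)}\t{min(ob)}\t{max(ob)}\n"
        )


def write_block_anchors_tsv(
    blocks: Sequence[SyntenyBlock], tag: str, dest: IO
) -> None:
    dest.write("comparison\tblock_id\tgene_a\tgene_b\n")
    for i, b in enumerate(blocks):
        for a in b.anchors:
            dest.write(f"{tag}\t{i}\t{a.gene_a}\t{a.gene_b}\n")


def render_dotplot(
    anchors: Sequence[AnchorPair],
    blocks: Sequence[SyntenyBlock],
    geneset_a: GeneSet,
    geneset_b: GeneSet,
    path: str,
) -> None:
    """Gene-ordinal vs gene-ordinal dot plot with blocks highlighted.

    Requires matplotlib (the ``plot`` extra); anchors are grey dots,
    block anchors coloured by orientation.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    def xy(pair: AnchorPair) -> tuple[int, int]:
        return geneset_a[pair.gene_a].ordinal, geneset_b[pair.gene_b].ordinal

    fig, ax = plt.subplots(figsize=(6, 6))
    pts = [xy(a) for a in anchors]
    ax.scatter([p[0] for p in pts], [p[1] for p in pts], s=3, c="0.8", label="anchors")
    for colour, orient in (("tab:blue", "+"), ("tab:red", "-")):
        bp = [xy(a) for b in blocks if b.orientation == orient for a in b.anchors]
        if bp:
            ax.scatter([p[0] for p in bp], [p[1] for p in bp], s=4, c=colour,
                       label=f"blocks {orient}")
    ax.set_xlabel(f"{geneset_a.species_tag} gene ordinal")
    ax.set_ylabel(f"{geneset_b.species_tag} gene ordinal")
    ax.legend(markerscale=3, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
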