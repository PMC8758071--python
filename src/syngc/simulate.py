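"""Synthetic genome pairs with known duplication history and ground truth.

Two gene-order genomes are derived from a common ancestor by applying,
per lineage, inversions, translocations, tandem and dispersed
duplications and gene losses.  A configurable fraction of ancestral genes
is "duplication-prone": dispersed duplications draw preferentially from
that class, and a dispersed duplication is followed half the time by loss
of the original copy — the route by which a gene leaves its ancestral
location.  The prone class carries a low third-codon-position GC target
and high methylation parameters, the resistant class a high GC target and
low methylation, reproducing the joint synteny/GC3/methylation pattern
the analysis is designed to detect: coding sequences are generated with
class-specific GC3 (bimodal, modes near 92% and 40% as in grass genomes),
and bisulfite calls with class-specific Beta-distributed methylation
sampled binomially at finite read depth.

Every output is reproducible: a single seed drives deterministic
per-stage substreams, so identical configs give byte-identical fixtures.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import pandas as pd

from syngc.formats_io import AnchorPair, GeneModel, GeneSet, MethylationCallSet
from syngc.methylation import assign_context

PRONE = "duplication_prone"
RESISTANT = "duplication_resistant"

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


#: per-class, per-context Beta(a, b) parameters of the true methylation level.
#: Prone-class CG mean 0.30, resistant 0.10; CHG and CHH lower, mirroring the
#: usual ordering of plant gene-end methylation.
DEFAULT_METH_BETA = {
    PRONE: {"CG": (1.5, 3.5), "CHG": (0.9, 5.1), "CHH": (0.5, 9.5)},
    RESISTANT: {"CG": (2.0 / 3.0, 6.0), "CHG": (0.3, 9.7), "CHH": (0.2, 19.8)},
}


@dataclass
class SimConfig:
    """Study conditions of the synthetic divergence scenario.

    The defaults describe a mid-sized plant-like gene space (3
    chromosomes x 1000 genes) with enough dispersed duplication-and-loss
    to give roughly a 2:1 syntenic:non-syntenic split and a true
    syntenic-minus-non-syntenic GC3-50 gap near 0.12, the magnitude
    observed between the two gene classes of grass genomes.
    """

    seed: int = 42
    n_chromosomes: int = 3
    genes_per_chromosome: int = 1000
    fraction_duplication_prone: float = 0.65
    n_inversions: int = 8
    n_translocations: int = 4
    n_dispersed_duplications: int = 600
    n_tandem_duplications: int = 100
    n_losses: int = 150
    inversion_len: tuple[int, int] = (10, 40)  # uniform range, genes
    translocation_len: tuple[int, int] = (10, 40)
    prone_odds: float = 4.0  # odds ratio for drawing dispersed-duplication sources
    loss_after_duplication: float = 0.5
    gc3_target_high: float = 0.92  # duplication-resistant class
    gc3_target_low: float = 0.40  # duplication-prone class
    meth_beta_params: dict = field(default_factory=lambda: {
        k: dict(v) for k, v in DEFAULT_METH_BETA.items()
    })
    read_depth: int = 30
    cds_codons: int = 60
    cds_codons_jitter: int = 40  # lengths drawn uniformly in [cds_codons, +jitter]
    spacer_len: int = 300
    min_block_size: int = 7  # truth-block floor, matching the detector's default
    truth_max_gap: int = 20

    def __post_init__(self) -> None:
        if not 0 <= self.fraction_duplication_prone <= 1:
            raise ValueError("fraction_duplication_prone must be in [0,1]")
        for name in ("n_inversions", "n_translocations", "n_dispersed_duplications",
                     "n_tandem_duplications", "n_losses"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        n = self.n_chromosomes * self.genes_per_chromosome
        if self.n_losses + self.n_dispersed_duplications > n:
            raise ValueError("rearrangement counts exceed genome size")


@dataclass
class SimTruth:
    """Ground truth of one simulated genome pair."""

    genes: pd.DataFrame  # gene_id, species, ancestor, class_label, origin, true_syntenic
    events: list[dict]
    true_blocks: dict[str, list[list[tuple[str, str]]]]  # species-pair tag -> blocks of pairs
    gc3_targets: dict[str, float]  # ancestor id -> third-position GC probability
    meth_levels: dict[str, dict[str, float]] = field(default_factory=dict)
    genome_seqs: dict[str, dict[str, str]] = field(default_factory=dict)

    def true_syntenic_ids(self, species: str) -> set[str]:
        df = self.genes
        sel = df[(df["species"] == species) & df["true_syntenic"]]
        return set(sel["gene_id"])


@dataclass
class _SimGene:
    """A gene occupying one slot of a simulated gene order."""

    gene_id: str
    ancestor: str
    class_label: str
    ancestral_locus: bool  # still at (or tandem-adjacent to) the ancestral position


def generate_cds(class_label: str, config: SimConfig, rng: np.random.Generator) -> str:
    """Random CDS with class-controlled third-position GC.

    Starts with ATG; codons 2..n draw their third base G or C with
    probability equal to the class GC3 target (G and C equiprobable) and
    A or T otherwise.  First/second codon positions come from a
    stop-avoiding alphabet: whenever position 1 is T, position 2 is
    restricted to C or T, which excludes TAA/TAG/TGA regardless of the
    third base.  No ambiguous bases are emitted.
    """
    target = (
        config.gc3_target_low if class_label == PRONE else config.gc3_target_high
    )
    n = config.cds_codons + int(rng.integers(0, config.cds_codons_jitter + 1))
    first = rng.choice(list("ACGT"), size=n - 1)
    second = np.where(
        first == "T",
        rng.choice(list("CT"), size=n - 1),
        rng.choice(list("ACGT"), size=n - 1),
    )
    gc = rng.random(n - 1) < target
    strong = rng.choice(list("GC"), size=n - 1)
    weak = rng.choice(list("AT"), size=n - 1)
    third = np.where(gc, strong, weak)
    codons = ["ATG"] + ["".join(t) for t in zip(first, second, third)]
    return "".join(codons)


def _apply_events(
    chroms: list[list[_SimGene]],
    tag: str,
    config: SimConfig,
    rng: np.random.Generator,
    events: list[dict],
) -> list[list[_SimGene]]:
    """Apply one lineage's rearrangements, duplications and losses in place."""
    def rand_chrom_with(minlen: int) -> Optional[int]:
        ok = [i for i, c in enumerate(chroms) if len(c) >= minlen]
        return int(rng.choice(ok)) if ok else None

    dup_counter = 0

    for _ in range(config.n_inversions):
        ln = int(rng.integers(*config.inversion_len, endpoint=True))
        ci = rand_chrom_with(ln)
        if ci is None:
            continue
        start = int(rng.integers(0, len(chroms[ci]) - ln + 1))
        chroms[ci][start : start + ln] = chroms[ci][start : start + ln][::-1]
        events.append({"type": "inversion", "lineage": tag, "chrom": ci,
                       "start": start, "length": ln})

    for _ in range(config.n_translocations):
        ln = int(rng.integers(*config.translocation_len, endpoint=True))
        ci = rand_chrom_with(ln)
        if ci is None:
            continue
        start = int(rng.integers(0, len(chroms[ci]) - ln + 1))
        segment = chroms[ci][start : start + ln]
        del chroms[ci][start : start + ln]
        cj = int(rng.integers(0, len(chroms)))
        pos = int(rng.integers(0, len(chroms[cj]) + 1))
        chroms[cj][pos:pos] = segment
        events.append({"type": "translocation", "lineage": tag, "from_chrom": ci,
                       "start": start, "length": ln, "to_chrom": cj, "to_pos": pos})

    for _ in range(config.n_tandem_duplications):
        ci = rand_chrom_with(1)
        pos = int(rng.integers(0, len(chroms[ci])))
        src = chroms[ci][pos]
        dup_counter += 1
        copy = _SimGene(f"{src.gene_id}_t{dup_counter}", src.ancestor,
                        src.class_label, ancestral_locus=True)
        chroms[ci].insert(pos + 1, copy)
        events.append({"type": "tandem_duplication", "lineage": tag,
                       "chrom": ci, "pos": pos, "source": src.gene_id})

    for _ in range(config.n_dispersed_duplications):
        flat = [(ci, gi) for ci, c in enumerate(chroms) for gi in range(len(c))]
        weights = np.array([
            config.prone_odds if chroms[ci][gi].class_label == PRONE else 1.0
            for ci, gi in flat
        ])
        weights /= weights.sum()
        ci, gi = flat[int(rng.choice(len(flat), p=weights))]
        src = chroms[ci][gi]
        dup_counter += 1
        copy = _SimGene(f"{src.gene_id}_d{dup_counter}", src.ancestor,
                        src.class_label, ancestral_locus=False)
        lose_original = bool(rng.random() < config.loss_after_duplication)
        cj = int(rng.integers(0, len(chroms)))
        pos = int(rng.integers(0, len(chroms[cj]) + 1))
        chroms[cj][pos:pos] = [copy]
        if lose_original:
            # re-locate the source: the insertion may have shifted it
            for ck, c in enumerate(chroms):
                for gk, g in enumerate(c):
                    if g.gene_id == src.gene_id:
                        del chroms[ck][gk]
                        break
                else:
                    continue
                break
        events.append({"type": "dispersed_duplication", "lineage": tag,
                       "source": src.gene_id, "to_chrom": cj, "to_pos": pos,
                       "original_lost": lose_original})

    for _ in range(config.n_losses):
        ci = rand_chrom_with(1)
        pos = int(rng.integers(0, len(chroms[ci])))
        lost = chroms[ci].pop(pos)
        events.append({"type": "loss", "lineage": tag, "chrom": ci,
                       "gene": lost.gene_id})

    return chroms


def _truth_blocks(
    chroms_a: list[list[_SimGene]],
    chroms_b: list[list[_SimGene]],
    config: SimConfig,
) -> list[list[tuple[str, str]]]:
    """Maximal ancestral-order-preserving runs between the two lineages.

    For every ancestor whose ancestral-locus copy survives in both
    lineages, the pair of those copies is a candidate; runs are maximal
    stretches, in genome-A order, whose partners stay on one B chromosome
    with monotone ordinals and bounded rank gaps on both sides.  Pairs
    orphaned at rearrangement junctions that still extend a neighbouring
    run under the same gap and monotonicity rule are absorbed into it
    (rearrangement endpoints occasionally land, by coincidence, within
    the rank-gap tolerance of another conserved segment).  Runs of at
    least ``min_block_size`` pairs are the true blocks.
    """
    def primary_positions(chroms):
        pos = {}
        for ci, c in enumerate(chroms):
            for gi, g in enumerate(c):
                if g.ancestral_locus and g.ancestor not in pos:
                    pos[g.ancestor] = (ci, gi, g.gene_id)
        return pos

    pa = primary_positions(chroms_a)
    pb = primary_positions(chroms_b)
    shared = sorted(set(pa) & set(pb), key=lambda anc: pa[anc][:2])

    # pairs as (a_chrom, a_ord, b_chrom, b_ord, gene_a, gene_b), in A order
    pairs = [
        (pa[anc][0], pa[anc][1], pb[anc][0], pb[anc][1], pa[anc][2], pb[anc][2])
        for anc in shared
    ]

    runs: list[list[tuple]] = []
    run: list[tuple] = []
    direction = 0
    for p in pairs:
        if run:
            q = run[-1]
            da = p[1] - q[1]
            db = p[3] - q[3]
            same = (
                p[0] == q[0]
                and p[2] == q[2]
                and 0 < da <= config.truth_max_gap
                and 0 < abs(db) <= config.truth_max_gap
                and (direction == 0 or np.sign(db) == direction)
            )
        else:
            same = False
        if same:
            if direction == 0:
                direction = int(np.sign(p[3] - run[-1][3]))
            run.append(p)
        else:
            runs.append(run)
            run = [p]
            direction = 0
    if run:
        runs.append(run)
    runs = [r for r in runs if r]

    cores = [r for r in runs if len(r) >= config.min_block_size]
    orphans = [p for r in runs if len(r) < config.min_block_size for p in r]

    def run_dir(r: list[tuple]) -> int:
        return int(np.sign(r[-1][3] - r[0][3])) if len(r) > 1 else 0

    changed = True
    while changed:
        changed = False
        for p in list(orphans):
            for r in cores:
                d = run_dir(r)
                head, tail = r[0], r[-1]
                fits_tail = (
                    p[0] == tail[0] and p[2] == tail[2]
                    and 0 < p[1] - tail[1] <= config.truth_max_gap
                    and 0 < d * (p[3] - tail[3]) <= config.truth_max_gap
                )
                fits_head = (
                    p[0] == head[0] and p[2] == head[2]
                    and 0 < head[1] - p[1] <= config.truth_max_gap
                    and 0 < d * (head[3] - p[3]) <= config.truth_max_gap
                )
                if fits_tail:
                    r.append(p)
                elif fits_head:
                    r.insert(0, p)
                else:
                    continue
                orphans.remove(p)
                changed = True
                break

    cores.sort(key=lambda r: (r[0][0], r[0][1]))
    return [[(p[4], p[5]) for p in r] for r in cores]


def _layout_genome(
    chroms: list[list[_SimGene]],
    tag: str,
    cds_by_ancestor: dict[str, str],
    config: SimConfig,
    rng: np.random.Generator,
) -> tuple[GeneSet, dict[str, str]]:
    """Place genes on chromosome sequences with random spacers."""
    genes: dict[str, GeneModel] = {}
    seqs: dict[str, str] = {}
    for ci, c in enumerate(chroms):
        chrom = f"chr{ci + 1}"
        parts: list[str] = []
        cursor = 0
        for gi, g in enumerate(c):
            spacer = "".join(rng.choice(list("ACGT"), size=config.spacer_len))
            parts.append(spacer)
            cursor += config.spacer_len
            cds = cds_by_ancestor[g.ancestor]
            strand = "+" if rng.random() < 0.5 else "-"
            parts.append(cds if strand == "+" else _revcomp(cds))
            genes[g.gene_id] = GeneModel(
                gene_id=g.gene_id, chrom=chrom, strand=strand,
                start=cursor, end=cursor + len(cds), ordinal=gi, cds=cds,
            )
            cursor += len(cds)
        parts.append("".join(rng.choice(list("ACGT"), size=config.spacer_len)))
        seqs[chrom] = "".join(parts)
    gs = GeneSet(species_tag=tag, genes=genes,
                 chrom_order=[f"chr{i + 1}" for i in range(len(chroms))])
    return gs, seqs


def generate_genome_pair(
    config: SimConfig,
) -> tuple[GeneSet, GeneSet, list[AnchorPair], SimTruth]:
    """Simulate an ancestor and two diverged descendant genomes.

    Returns the two gene sets (species tags ``A`` and ``B``), the anchor
    list of all homologous pairs (duplicates included), and the ground
    truth (per-gene labels, event log, true blocks, genome sequences).
    """
    ss = np.random.SeedSequence(config.seed)
    rng_class, rng_cds, rng_a, rng_b, rng_layout_a, rng_layout_b = (
        np.random.default_rng(s) for s in ss.spawn(6)
    )

    n = config.n_chromosomes * config.genes_per_chromosome
    classes = np.where(
        rng_class.random(n) < config.fraction_duplication_prone, PRONE, RESISTANT
    )
    ancestors = [f"anc{i:05d}" for i in range(n)]
    cds_by_ancestor = {
        anc: generate_cds(cls, config, rng_cds) for anc, cls in zip(ancestors, classes)
    }
    gc3_targets = {
        anc: (config.gc3_target_low if cls == PRONE else config.gc3_target_high)
        for anc, cls in zip(ancestors, classes)
    }

    def fresh_lineage(tag: str) -> list[list[_SimGene]]:
        chroms = []
        for ci in range(config.n_chromosomes):
            lo = ci * config.genes_per_chromosome
            hi = lo + config.genes_per_chromosome
            chroms.append([
                _SimGene(f"{tag}_{ancestors[i]}", ancestors[i], classes[i], True)
                for i in range(lo, hi)
            ])
        return chroms

    events: list[dict] = []
    chroms_a = _apply_events(fresh_lineage("A"), "A", config, rng_a, events)
    chroms_b = _apply_events(fresh_lineage("B"), "B", config, rng_b, events)

    gs_a, seqs_a = _layout_genome(chroms_a, "A", cds_by_ancestor, config, rng_layout_a)
    gs_b, seqs_b = _layout_genome(chroms_b, "B", cds_by_ancestor, config, rng_layout_b)

    by_anc_a: dict[str, list[str]] = {}
    for c in chroms_a:
        for g in c:
            by_anc_a.setdefault(g.ancestor, []).append(g.gene_id)
    by_anc_b: dict[str, list[str]] = {}
    for c in chroms_b:
        for g in c:
            by_anc_b.setdefault(g.ancestor, []).append(g.gene_id)
    anchors = [
        AnchorPair(ga, gb)
        for anc in sorted(set(by_anc_a) & set(by_anc_b))
        for ga in by_anc_a[anc]
        for gb in by_anc_b[anc]
    ]

    blocks = _truth_blocks(chroms_a, chroms_b, config)
    in_block_a = {a for blk in blocks for a, _ in blk}
    in_block_b = {b for blk in blocks for _, b in blk}

    # tandem copies adjacent to an in-block primary inherit its status,
    # exactly as the detector propagates status through collapsed arrays
    def syntenic_flag(g: _SimGene, in_block: set[str], tag: str) -> bool:
        if g.gene_id in in_block:
            return True
        if g.ancestral_locus:
            primary = f"{tag}_{g.ancestor}"
            return primary in in_block
        return False

    records = []
    for tag, chroms in (("A", chroms_a), ("B", chroms_b)):
        in_block = in_block_a if tag == "A" else in_block_b
        for c in chroms:
            for g in c:
                origin = (
                    "ancestral" if g.gene_id == f"{tag}_{g.ancestor}"
                    else ("tandem" if g.ancestral_locus else "dispersed")
                )
                records.append({
                    "gene_id": g.gene_id,
                    "species": tag,
                    "ancestor": g.ancestor,
                    "class_label": g.class_label,
                    "origin": origin,
                    "true_syntenic": syntenic_flag(g, in_block, tag),
                })

    truth = SimTruth(
        genes=pd.DataFrame.from_records(records),
        events=events,
        true_blocks={"A-B": blocks},
        gc3_targets=gc3_targets,
        genome_seqs={"A": seqs_a, "B": seqs_b},
    )
    return gs_a, gs_b, anchors, truth


def simulate_bisulfite_calls(
    gene_set: GeneSet,
    truth: SimTruth,
    config: SimConfig,
    region_len: int = 150,
) -> MethylationCallSet:
    """Read-level bisulfite calls over every gene's 5' region.

    For each cytosine (both strands) within the first ``region_len``
    transcript bases, the per-gene per-context true level is drawn from
    the class Beta distribution and reads are sampled
    Binomial(read_depth, level).  Drawn levels are recorded in
    ``truth.meth_levels``.
    """
    tag = gene_set.species_tag
    seqs = truth.genome_seqs[tag]
    class_of = dict(zip(truth.genes["gene_id"], truth.genes["class_label"]))
    ss = np.random.SeedSequence((config.seed, sum(tag.encode())))
    rng = np.random.default_rng(ss)

    rows = []
    for gid in sorted(gene_set.genes):
        gene = gene_set[gid]
        cls = class_of[gid]
        params = config.meth_beta_params[cls]
        levels = {
            ctx: float(rng.beta(*params[ctx])) for ctx in ("CG", "CHG", "CHH")
        }
        truth.meth_levels[gid] = levels
        if gene.strand == "+":
            lo, hi = gene.start, min(gene.end, gene.start + region_len)
        else:
            lo, hi = max(gene.start, gene.end - region_len), gene.end
        seq = seqs[gene.chrom]
        for pos0 in range(lo, hi):
            base = seq[pos0]
            for strand, is_c in (("+", base == "C"), ("-", base == "G")):
                if not is_c:
                    continue
                ctx = assign_context(seqs, gene.chrom, pos0 + 1, strand)
                if ctx is None:
                    continue
                total = config.read_depth
                m = int(rng.binomial(total, levels[ctx])) if total > 0 else 0
                rows.append((gene.chrom, pos0 + 1, strand, ctx, m, total))

    df = pd.DataFrame(rows, columns=["chrom", "pos", "strand", "context",
                                     "m_reads", "total_reads"])
    df = df.drop_duplicates(subset=["chrom", "pos", "strand"], keep="first")
    df = df.sort_values(["chrom", "pos", "strand"]).reset_index(drop=True)
    df["covered"] = df["total_reads"] > 0
    return MethylationCallSet(df)


def generate_go_map(
    truth: SimTruth,
    species: str,
    n_terms: int = 30,
    n_biased: int = 6,
    mean_terms_per_gene: float = 2.0,
    seed: int = 0,
) -> dict[str, list[str]]:
    """Synthetic gene->GO-term map with a few class-biased terms.

    The first ``n_biased`` terms are enriched in the duplication-resistant
    (mostly syntenic) class and the next ``n_biased`` in the prone class,
    giving the enrichment scan a known signal; remaining terms are drawn
    uniformly.
    """
    rng = np.random.default_rng((seed, 97))
    df = truth.genes[truth.genes["species"] == species]
    terms = [f"GO:{i + 1:07d}" for i in range(n_terms)]
    out: dict[str, list[str]] = {}
    for gid, cls in zip(df["gene_id"], df["class_label"]):
        k = min(n_terms, rng.poisson(mean_terms_per_gene))
        if k == 0:
            continue
        w = np.ones(n_terms)
        if cls == RESISTANT:
            w[:n_biased] = 4.0
        else:
            w[n_biased : 2 * n_biased] = 4.0
        w /= w.sum()
        chosen = rng.choice(n_terms, size=k, replace=False, p=w)
        out[gid] = [terms[i] for i in sorted(chosen)]
    return out


def write_fixture(outdir, config: SimConfig, with_go: bool = True) -> dict:
    """Generate a complete on-disk fixture runnable by the pipeline.

    Writes per-species genome FASTA, CDS FASTA, GFF3 and allc tables, the
    anchor TSV, truth tables and the config; returns the paths.
    """
    import os

    os.makedirs(outdir, exist_ok=True)
    gs_a, gs_b, anchors, truth = generate_genome_pair(config)
    paths = {"dir": str(outdir)}

    def p(name: str) -> str:
        paths[name] = os.path.join(outdir, name)
        return paths[name]

    for tag, gs in (("A", gs_a), ("B", gs_b)):
        with open(p(f"genome_{tag}.fa"), "w") as fh:
            for chrom in gs.chrom_order:
                fh.write(f">{chrom}\n{truth.genome_seqs[tag][chrom]}\n")
        with open(p(f"cds_{tag}.fa"), "w") as fh:
            for gid in sorted(gs.genes):
                fh.write(f">{gid}.1\n{gs[gid].cds}\n")
        with open(p(f"genes_{tag}.gff3"), "w") as fh:
            fh.write("##gff-version 3\n")
            for chrom in gs.chrom_order:
                for g in sorted(
                    (g for g in gs.genes.values() if g.chrom == chrom),
                    key=lambda g: g.ordinal,
                ):
                    fh.write(
                        f"{g.chrom}\tsim\tgene\t{g.start + 1}\t{g.end}\t.\t"
                        f"{g.strand}\t.\tID={g.gene_id}\n"
                    )
                    fh.write(
                        f"{g.chrom}\tsim\tmRNA\t{g.start + 1}\t{g.end}\t.\t"
                        f"{g.strand}\t.\tID={g.gene_id}.1;Parent={g.gene_id}\n"
                    )
        calls = simulate_bisulfite_calls(gs, truth, config)
        calls.df.drop(columns=["covered"]).to_csv(
            p(f"allc_{tag}.tsv"), sep="\t", header=False, index=False
        )

    with open(p("anchors_A_B.tsv"), "w") as fh:
        for a in anchors:
            fh.write(f"{a.gene_a}\t{a.gene_b}\n")

    truth.genes.to_csv(p("truth_genes.tsv"), sep="\t", index=False)
    with open(p("truth_blocks.tsv"), "w") as fh:
        fh.write("comparison\tblock_id\tgene_a\tgene_b\n")
        for tag, blocks in truth.true_blocks.items():
            for i, blk in enumerate(blocks):
                for ga, gb in blk:
                    fh.write(f"{tag}\t{i}\t{ga}\t{gb}\n")
    with open(p("sim_config.json"), "w") as fh:
        json.dump(asdict(config), fh, indent=2, default=list)

    if with_go:
        go_map = generate_go_map(truth, "A", seed=config.seed)
        with open(p("go_A.tsv"), "w") as fh:
            for gid in sorted(go_map):
                for term in go_map[gid]:
                    fh.write(f"{gid}\t{term}\n")
    return paths


def packaged_fixture_config() -> SimConfig:
    """The canonical small fixture: 2 chromosomes x 60 genes, seed 42.

    Small enough to regenerate in well under a second; used by the test
    suite and the worked example rather than shipping static files.
    """
    return SimConfig(
        seed=42,
        n_chromosomes=2,
        genes_per_chromosome=60,
        n_inversions=1,
        n_translocations=1,
        n_dispersed_duplications=15,
        n_tandem_duplications=4,
        n_losses=5,
        inversion_len=(8, 15),
        translocation_len=(8, 15),
    )
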