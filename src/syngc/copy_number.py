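"""Within-genome copy number of gene 5' ends.

The repetitiveness of each gene is estimated by searching the genome
assembly for high-similarity copies of the first 150 bp of its CDS and
binning the hit count into three classes: single copy (1), moderately
repetitive (2-9 copies) and repetitive (10+ copies).  The gene's own
locus is always found, so every gene has at least one hit.

The built-in matcher is an ungapped seed-and-extend scan (exact 12-mer
seeds, identity >= 90% over >= 90% of the query, both strands, overlapping
hits merged into loci) standing in for a high-stringency BLASTN search; a
precomputed BLAST tabular file can be supplied instead and is counted
with the same locus-merging rule.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

SINGLE = "single"
MODERATE = "moderate"
REPETITIVE = "repetitive"

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

SEED_LEN = 12


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class CopyNumberResult:
    gene_id: str
    n_hits: int
    copy_class: str


def bin_copy_number(n_hits: int) -> str:
    """Bin a hit count into the single / 2-9 / 10+ repetitiveness classes."""
    if n_hits < 1:
        raise ValueError("n_hits must be >= 1 (the gene's own locus always counts)")
    if n_hits == 1:
        return SINGLE
    if n_hits <= 9:
        return MODERATE
    return REPETITIVE


class GenomeIndex:
    """Exact k-mer index over a set of chromosome sequences.

    Positions are recorded per chromosome on the forward strand; queries
    are searched in both orientations by scanning the reverse complement
    of the query.
    """

    def __init__(self, chroms: Mapping[str, str], k: int = SEED_LEN):
        self.k = k
        self.chroms = {c: s.upper() for c, s in chroms.items()}
        self.index: dict[str, list[tuple[str, int]]] = {}
        for chrom, seq in self.chroms.items():
            for i in range(len(seq) - k + 1):
                self.index.setdefault(seq[i : i + k], []).append((chrom, i))


def _identity_at(query: str, target: str, offset: int) -> tuple[float, float, int, int]:
    """Ungapped identity of the query laid on the target at ``offset``.

    Negative offsets and overhangs past the target end truncate the
    aligned span; returns (identity over aligned bases, aligned fraction
    of the query, span start, span end).
    """
    qlen = len(query)
    qs = max(0, -offset)
    qe = min(qlen, len(target) - offset)
    if qe <= qs:
        return 0.0, 0.0, 0, 0
    matches = sum(
        1 for i in range(qs, qe) if query[i] == target[offset + i]
    )
    aligned = qe - qs
    return matches / aligned, aligned / qlen, offset + qs, offset + qe


def _merge_loci(spans: list[tuple[str, int, int]]) -> int:
    """Count distinct loci after merging spans overlapping by >= 50%.

    Spans on different chromosomes never merge; overlap fraction is
    measured relative to the shorter span so a locus hit on both strands
    counts once.
    """
    loci: list[tuple[str, int, int]] = []
    for chrom, s, e in sorted(spans):
        merged = False
        for i, (c2, s2, e2) in enumerate(loci):
            if c2 != chrom:
                continue
            ov = min(e, e2) - max(s, s2)
            if ov >= 0.5 * min(e - s, e2 - s2):
                loci[i] = (c2, min(s, s2), max(e, e2))
                merged = True
                break
        if not merged:
            loci.append((chrom, s, e))
    return len(loci)


def count_genome_hits(
    query: str,
    genome: GenomeIndex,
    min_identity: float = 0.90,
    min_coverage: float = 0.90,
) -> int:
    """Number of genomic loci matching the query at high stringency.

    The query (first 150 bp of a gene's CDS) is seeded with exact
    12-mers against both strands; each candidate diagonal is scored by
    ungapped identity, and hits reaching ``min_identity`` over
    ``min_coverage`` of the query are merged into loci.
    """
    q = query.upper()
    if len(q) < 50:
        raise ValueError("query shorter than 50 bp after trimming")
    k = genome.k
    spans: list[tuple[str, int, int]] = []
    for oriented in (q, revcomp(q)):
        seen_offsets: dict[str, set[int]] = {}
        for qpos in range(0, len(oriented) - k + 1):
            seed = oriented[qpos : qpos + k]
            for chrom, tpos in genome.index.get(seed, ()):
                offset = tpos - qpos
                if offset in seen_offsets.setdefault(chrom, set()):
                    continue
                seen_offsets[chrom].add(offset)
                ident, cov, s, e = _identity_at(oriented, genome.chroms[chrom], offset)
                if ident >= min_identity and cov >= min_coverage:
                    spans.append((chrom, s, e))
    return _merge_loci(spans)


def count_hits_from_blast(
    rows: Sequence[Mapping], max_evalue: float = 1e-30
) -> int:
    """Count loci from precomputed BLAST tabular rows for one query.

    Each row needs ``sseqid``, ``sstart``, ``send`` and ``evalue`` (outfmt
    6 naming); hits above the E-value cutoff are dropped and the remainder
    merged into loci exactly as the internal matcher does.
    """
    spans = []
    for row in rows:
        if float(row["evalue"]) >= max_evalue:
            continue
        s, e = int(row["sstart"]), int(row["send"])
        if s > e:
            s, e = e, s
        spans.append((str(row["sseqid"]), s - 1, e))
    return _merge_loci(spans)


def classify_copy_number(
    gene_id: str,
    cds: Optional[str],
    genome: GenomeIndex,
    query_len: int = 150,
    min_identity: float = 0.90,
    min_coverage: float = 0.90,
) -> Optional[CopyNumberResult]:
    """Copy-number class of one gene from the 5' ``query_len`` bp of its CDS.

    Returns None when the gene has no usable CDS of at least 50 bp.
    """
    if not cds or len(cds) < 50:
        return None
    n = count_genome_hits(cds[:query_len], genome, min_identity, min_coverage)
    n = max(n, 1)  # the gene's own locus exists even if soft-masked in the assembly
    return CopyNumberResult(gene_id, n, bin_copy_number(n))
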