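"""Third-codon-position GC content (GC3) statistics.

GC3 in plant genes declines with distance from the start codon, which
couples whole-gene GC3 to gene length.  GC3-50 — GC3 over the first 50
codons only — removes that length dependence and is the statistic used
throughout this package.  Genes shorter than 50 codons, genes containing
ambiguous bases and genes not starting with ATG are excluded before any
GC3 value is computed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from syngc.formats_io import GeneSet

PASS = "pass"
TOO_SHORT = "too_short"
AMBIGUOUS = "ambiguous_base"
NO_ATG = "no_atg"

_STOPS = {"TAA", "TAG", "TGA"}
_ACGT = set("ACGT")


@dataclass
class GeneGC:
    gene_id: str
    filter_status: str
    gc3_50: Optional[float] = None
    gc3_full: Optional[float] = None
    n_codons: int = 0


def filter_cds(cds: str) -> str:
    """Classify a CDS against the composition filters.

    Returns ``pass``, or the first failing filter in the fixed precedence
    too_short > no_atg > ambiguous_base.  The ambiguity check covers the
    whole CDS, not only the first 50 codons.
    """
    if not cds:
        raise ValueError("empty CDS")
    seq = cds.upper()
    if len(seq) // 3 < 50:
        return TOO_SHORT
    if seq[:3] != "ATG":
        return NO_ATG
    if set(seq) - _ACGT:
        return AMBIGUOUS
    return PASS


def gc3_50(cds: str) -> float:
    """GC fraction at third codon positions of codons 1-50.

    Codon 1 (ATG) is included, so its G puts a floor of 0.02 on every
    gene; values lie on the 2% lattice {0, 0.02, ..., 1.0}.
    """
    seq = cds.upper()
    if filter_cds(seq) != PASS:
        raise ValueError("gc3_50 called on a gene failing the CDS filters")
    third = seq[2:150:3]
    return sum(c in "GC" for c in third) / 50.0


def gc3_full(cds: str) -> float:
    """GC fraction at third positions of all complete codons.

    A terminal stop codon (TAA/TAG/TGA at the very end) is excluded from
    the denominator; stop codons are constrained (two of three end in A)
    and would otherwise bias short genes.
    """
    seq = cds.upper()
    if filter_cds(seq) != PASS:
        raise ValueError("gc3_full called on a gene failing the CDS filters")
    n = len(seq) // 3
    if n and seq[3 * (n - 1): 3 * n] in _STOPS:
        n -= 1
    third = seq[2: 3 * n: 3]
    return sum(c in "GC" for c in third) / n


def compute_gene_gc(gene_id: str, cds: Optional[str]) -> GeneGC:
    """Filter one gene's CDS and compute its GC3 statistics if it passes."""
    if not cds:
        return GeneGC(gene_id, TOO_SHORT)
    status = filter_cds(cds)
    if status != PASS:
        return GeneGC(gene_id, status, n_codons=len(cds) // 3)
    return GeneGC(gene_id, PASS, gc3_50(cds), gc3_full(cds), len(cds) // 3)


def compute_gc_table(gene_set: GeneSet) -> dict[str, GeneGC]:
    return {gid: compute_gene_gc(gid, g.cds) for gid, g in gene_set.genes.items()}


def positional_gc3_profile(
    gene_set: GeneSet, max_codon: int = 300
) -> pd.DataFrame:
    """Mean third-position GC indicator per codon index across passing genes.

    For codon index i (1-based), the mean over genes with at least i
    complete codons of the indicator {third base of codon i is G or C},
    together with the number of contributing genes.
    """
    sums = np.zeros(max_codon)
    counts = np.zeros(max_codon, dtype=int)
    any_pass = False
    for g in gene_set.genes.values():
        if not g.cds or filter_cds(g.cds) != PASS:
            continue
        any_pass = True
        seq = g.cds.upper()
        third = seq[2::3][:max_codon]
        k = len(third)
        arr = np.frombuffer(third.encode(), dtype=np.uint8)
        sums[:k] += (arr == ord("G")) | (arr == ord("C"))
        counts[:k] += 1
    if not any_pass:
        raise ValueError("no passing genes")
    with np.errstate(invalid="ignore"):
        mean = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return pd.DataFrame(
        {"codon_index": np.arange(1, max_codon + 1), "mean_gc3": mean, "n_genes": counts}
    )
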